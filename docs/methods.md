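# Methods

## Scope and data model

The pipeline starts at variant count tables: per (tile, condition,
replicate) read counts for every protein-level variant, with conditions
`pre`, `post`, and `wt_control`. Read-level processing (alignment, posterior
base calling, tile demultiplexing) is upstream of this package, as are the
structural computations (solvent exposure, interface calls, ΔΔG
prediction) whose outputs are consumed as per-position or per-variant
tables.

Variants are identified throughout by three-letter HGVS-like protein
notation (`p.Ala5Val`); one-letter notation is accepted on input and a
mapping table can be emitted for MaveDB interoperability. The variant class
is structural: nonsense iff the alternate residue is a stop, synonymous iff
it equals the reference, missense otherwise. The initiator-methionine
position and stops at the final codon are enumerated but flagged and
excluded from scoring by default: start-loss is not a missense map entry,
and a terminal stop cannot anchor the nonsense median meaningfully.

## Scoring model

**Frequencies and filters.** Counts become reads-per-million frequencies.
A variant is dropped in a replicate when its pre-selection count is below
10 or its pre-selection frequency does not exceed the 90th percentile of
the wild-type-control frequencies of its tile; the percentile rule is
stratified per tile because error rates are tile-specific in tiled
amplicon designs, and the control frequencies of all variants in the tile
are pooled. A variant is *well measured* when its pre-selection frequency
is at least 10 reads per million. With an all-zero control (no measurable
error background) the percentile rule excludes nothing.

**Error-corrected enrichment.** The mean wild-type-control frequency per
variant is subtracted from both pre- and post-selection frequencies before
the ratio. Enrichment is worked in log₂ — the final score is
base-invariant after rescaling, so the base only affects intermediate
values. A non-positive corrected pre-selection frequency makes the variant
unmeasurable in that replicate (absence from the input pool is
uninformative), while a non-positive corrected post-selection frequency is
floored at a half-read pseudo-frequency (depletion to zero is informative,
and the floor bounds the log). Variances follow Poisson counting noise,
Var(f) = f·10⁶/D in ppm², summed through the subtraction (the control
variance shrinks with the number of pooled control replicates) and pushed
through the log by the delta method.

**Rescaling.** Within each replicate, scores are the affine transform
placing the median nonsense log-enrichment at 0 and the median synonymous
log-enrichment at 1; standard errors scale by the same positive factor. At
least 10 measurable anchors of each class are required (configurable), and
a synonymous median at or below the nonsense median raises a
"no selection separation" error — the screen has failed and no rescaling is
meaningful. The midpoint of the anchors, 0.5, is the deleteriousness
cutoff used by every downstream analysis, with a strict `< 0.5` rule so
boundary scores count as tolerated.

**Error regularization.** Per-variant delta-method errors are noisy, so
log₁₀(se) is regressed on log₁₀(pre-selection frequency) by least absolute
deviations (median regression; robust to the heavy upper tail of error
estimates) within each replicate, and each variant's variance is shrunk
toward the trend with a prior weight of m = 2 pseudo-replicates:
var = (m·se²_model + df·se²_emp)/(m + df), df → m + df. This removes
zero-variance artifacts (identical replicate draws) without flattening
genuine heteroscedasticity. Below 30 usable variants the fit is skipped
and empirical errors pass through with a warning.

**Replicate combination.** Inverse-variance weights, se = (Σ 1/se²)^(-1/2),
degrees of freedom by Welch–Satterthwaite. Single-replicate variants carry
their replicate's se and df unchanged; variants with no measurable
replicate are absent from the map.

## Generative screen model

The synthetic generator defines the study conditions the tests run under.
Defaults: 154-codon ORF in 5 tiles (~31 codons each, the tiled-amplicon
geometry of a SOD1-sized gene), 2 biological replicates, 2×10⁵ reads per
tile per condition — a deliberate scale-down of the >1.3×10⁶ reads/tile of
a production screen that keeps the full suite fast while leaving tens of
reads on a typical variant.

- **True effects**: synonymous ≡ 1, nonsense ≡ 0; missense from a
  two-component normal mixture, θ = 0.3 deleterious (between the ~25%
  activity and ~33% abundance deleterious fractions of published dual
  maps), components N(0, 0.15) and N(1, 0.15), clipped to [−0.5, 1.5] so
  above-wild-type ("hyper") scores exist while the mixture stays proper.
- **Library composition**: a Poisson per-cell codon substitution load
  (0.64 growth / 0.83 gate by default) apportioned to tiles by codon
  count sets each tile's mutant read fraction; within a tile, variant
  shares follow log-normal clone-multiplicity weights whose coefficient
  of variation shrinks as 1/√(clones per variant), 50 by default — the
  ≥50-independent-clones complexity target of the mutagenesis protocol.
  The Poisson load also yields the multi-mutant clone fraction as a
  diagnostic; explicit multi-mutant genotypes and their marginal-count
  confounding are not simulated.
- **Selection**: growth assays multiply pre-selection frequencies by
  B^score with B = 32 (five log₂ units of separation between null and
  wild-type-like variants over the selection, a strong
  temperature-restrictive regime); the functional form linking growth to
  score is a stand-in isolated behind the assay interface. Gate (FACS)
  assays use a logistic pass probability with midpoint 0.5 and slope 8 —
  the minimal smooth gate for a "high-fluorescence" sort.
- **Error background**: each substitution reachable by a single base
  miscall from the reference codon receives a constant control frequency
  (2 ppm default), added to all three conditions; other substitutions get
  none. This mimics the structure of base-calling error without
  read-level simulation.
- **Sampling**: one multinomial draw of the tile depth per condition and
  replicate, with the wild-type read share as an unreported remainder, so
  variant counts sum to at most the depth.

What the generator does *not* emulate: read-level errors correlated across
conditions, PCR jackpotting beyond log-normal dispersion, tile-boundary
edge effects, replicate-specific selection intensity drift, and
contaminated clinical labels. Passing tests therefore demonstrate the
correctness and calibration of the *computation*, not the biological
fidelity of any particular screen.

Synthetic reference sets draw positives from the low-true-effect half of
missense variants and negatives from the high half; an `overlap` parameter
interpolates to labels independent of effect (overlap = 1), giving a
permutation null for benchmark statistics.

## Clinical calibration

Balanced precision weighs the positive and negative reference sets 50/50
by Bayes' rule: with π = 0.5, balanced precision =
recall/(recall + FPR), which reduces algebraically to ordinary precision
when the sets are equal-sized. Curves enumerate every unique score
threshold (call = score ≤ threshold; lower score = more pathogenic, as
both assays are loss signals). AUBPRC integrates balanced precision over
recall by trapezoid, extending to recall 0 with the tightest informative
threshold's precision and to recall 1 with the loosest; R80BP is the
maximum recall at balanced precision ≥ 0.80.

LLRp uses Epanechnikov kernel density estimates of the positive and
negative reference score distributions. The Sheather–Jones
solve-the-equation bandwidth is computed in its native Gaussian-kernel
form and converted by the canonical-bandwidth ratio
((R_E/μ²₂,E)/(R_G/μ²₂,G))^{1/5} ≈ 2.214, since a direct SJ solve for
non-Gaussian kernels is not standard; the implementation is cross-checked
against R's `bw.SJ` in the test suite. Both densities are floored at
1/(10·n·range) before the ratio so LLRp stays finite outside one set's
support; floored evaluations are flagged. Confidence intervals come from
a percentile bootstrap over reference-set resampling (default 1000
resamples, seeded). A caveat: the percentile bootstrap captures sampling
variation but not KDE smoothing bias, so coverage degrades where the true
log-ratio is steep relative to the bandwidth — the tests estimate coverage
in the overlap region of the two distributions, where the estimator is
consistent.

LLRp is reported in log₁₀ so the Tavtigian combined-odds constant
O_PVSt = 350 applies directly: pathogenic evidence thresholds at
log₁₀350 × {⅛, ¼, ½, 1} (supporting → very strong), benign thresholds
mirrored with negative sign (supporting → strong). The prior (default 0.1)
and odds constant are configurable, as adapted calibrations vary between
frameworks.

## Map analyses

Quadrant classification joins two maps on well-measured missense variants
and applies the strict 0.5 rule in each; the dominant per-position
quadrant is a strict plurality with ties reported as none. Positional
profiles aggregate measured missense scores by median (structure
contrasts) or mean (phenotype comparison). Group contrasts use the
two-sided Mann-Whitney U test, exact by enumeration when both groups have
≤ 8 members, normal approximation otherwise, with Benjamini-Hochberg
adjustment across pairs (the adjustment method is a package choice;
alternatives can be applied to the raw p-values). Burial classes use the
35% (exposed) / 20% (buried) relative-solvent-exposure thresholds;
stability classes use the ΔΔG > −0.1 (stabilizing-or-neutral) and
ΔΔG < −0.5 (destabilizing) thresholds with the negative-is-destabilizing
sign convention. Stable-but-inactive variants are those deleterious in the
map whose ΔΔG is stabilizing-or-neutral. Moving windows default to 10
positions, step 1. Depletion odds ratios use a Haldane-Anscombe 0.5
correction only when a cell is zero, and the Fisher exact p-value is
computed on the uncorrected table. Phenotype tables aggregate multi-study
values by sample-size-weighted average; correlations default to Spearman
for robustness, with Pearson available.

## Numerical choices and degenerate inputs

- Medians use the standard linear-interpolation convention throughout.
- Ties in quantile thresholds are resolved by the strict `>` comparison of
  the filter rule (a frequency equal to the control percentile is
  excluded).
- Zero depth, empty files, unknown condition tokens, duplicate variants,
  label clashes, and overlapping feature groups are errors, not warnings.
- Single-point curves, all-zero controls, and too-few-anchor replicates
  degrade explicitly (warning or error) rather than silently.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Problem sizes used in tests

The default test configuration scores the full 154-codon substitution
space (2,926 missense + 154 nonsense + 154 synonymous entries) at 2×10⁵
reads per tile with 2 replicates; calibration checks use two-normal
reference sets of 100–500 scores per label with 400-resample bootstraps,
and the permutation null uses 100 label-independent sets of 500/500.
These sizes recover true effects at Pearson r ≈ 0.98 and keep the whole
suite under a minute.

## Known limitations

- The growth-to-score exponential link and the logistic gate are modeling
  stand-ins; inference about real screens should treat the absolute scale
  of simulated selection as arbitrary.
- Scores below the anchor floor or above wild type are reported as-is;
  no shrinkage toward the [0, 1] interval is applied.
- The LLR bootstrap resamples reference variants, not the underlying
  assay noise; assay-level uncertainty enters only through the score map.
- Multi-mutant clones, tile-edge artifacts, and replicate-correlated
  errors are outside the generative model (see above).
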