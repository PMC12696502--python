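# mavemap

Scoring, analysis, and clinical calibration of **variant-effect maps** from
multiplexed assays of variant effect (MAVE / deep mutational scanning), in
the style of TileSeq enzymatic-activity screens and VAMP-seq abundance
screens such as those used to map human SOD1 missense variation.

The package takes per-tile variant read-count tables (pre-selection,
post-selection, and a wild-type sequencing control, over biological
replicates) and turns them into a rescaled functional-score map, then
supports the downstream analyses a variant-effect-mapping study needs:
joint activity/abundance quadrant classification, positional and
substitution profiles, stability (ΔΔG) concordance, population depletion
odds ratios, genotype-phenotype correlation, balanced precision-recall
benchmarking against clinical reference sets, and transformation of scores
into log-likelihood ratios of pathogenicity with ACMG/AMP-style evidence
strengths. A synthetic-screen generator makes every stage testable without
any external data.

## The model

For variant *v* in replicate *r*, with read frequencies *f* (reads per
million) and a wild-type control frequency *f*<sub>WT</sub> capturing
base-call error:

- error-corrected enrichment: φ = (*f*<sub>post</sub> − *f*<sub>WT</sub>) /
  (*f*<sub>pre</sub> − *f*<sub>WT</sub>), worked in log₂;
- rescaling: *s* = (log φ − median<sub>nonsense</sub>) /
  (median<sub>synonymous</sub> − median<sub>nonsense</sub>), so nonsense
  variants sit at 0 (null) and synonymous at 1 (wild-type-like), and a
  score < 0.5 is called deleterious;
- uncertainty: Poisson counting noise propagated by the delta method,
  regularized against the log-linear trend of error versus pre-selection
  frequency, then replicates combined by inverse-variance weighting with
  Welch–Satterthwaite degrees of freedom.

For clinical calibration, densities of the pathogenic (P/LP) and benign
(B/PB) reference score sets are estimated with an Epanechnikov kernel and
Sheather–Jones bandwidths, giving LLRp(*s*) = log₁₀ *d*₊(*s*)/*d*₋(*s*),
which is mapped onto the Tavtigian combined-odds ladder
(log₁₀ 350 × {1, ½, ¼, ⅛}) for very-strong/strong/moderate/supporting
evidence in either direction.

## Worked example

Simulate a two-replicate growth screen of a SOD1-sized (154-codon) ORF,
score it, and calibrate against a synthetic reference set:

```sh
mavemap simulate --seed 7 --n-codons 154 \
    --out-counts counts.tsv --out-effects effects.tsv
# wrote 19404 count rows, 3234 effects
mavemap score --counts counts.tsv --effects effects.tsv --out scores.csv
# scored 3212 variants; anchors per replicate:
#   {"1": [-5.1699, 0.1125], "2": [-5.1699, 0.0608]}
mavemap calibrate curve --scores scores.csv --reference refs.csv --out curve.tsv
# {"aubprc": 0.9690, "r80bp": 1.0}
```

The anchors are the per-replicate nonsense and synonymous log₂-enrichment
medians the rescaling pins to 0 and 1: nonsense variants deplete about
5.2 log₂ units over the selection while synonymous variants track wild
type. The score CSV is MaveDB-style:

```
hgvs_pro,score,se,df,klass,n_replicates,well_measured
p.Ala106Ala,0.9627,0.0462,5.87,synonymous,2,True
p.Ala106Arg,0.9338,0.0442,5.91,missense,2,True
```

AUBPRC (area under the balanced precision-recall curve, precision
re-weighted to a 50/50 pathogenic prior) of 0.97 and recall of 1.0 at 80%
balanced precision reflect the cleanly separable synthetic labels; real
clinical reference sets are noisier. `mavemap calibrate llr` adds per
variant LLRp with bootstrap confidence intervals and the evidence category.

The same operations are available as a library, including sklearn-style
estimators (`TileSeqScorer`, `LlrCalibrator`) that compose with sklearn
model-selection tooling:

```python
from mavemap import TileSeqScorer, LlrCalibrator
vmap = TileSeqScorer().fit_transform(counts, variant_info=effects)
cal = LlrCalibrator().fit(ref_scores, ref_labels)
llr = cal.predict(vmap["score"])
```

## Layout

- `mavemap.variants` — ORF/tile model, HGVS-like protein notation, NNK and
  SNV accessibility of the substitution space
- `mavemap.simulate` — generative screen model and synthetic reference sets
- `mavemap.scoring` — frequencies → filters → enrichment → rescaling →
  error regularization → replicate combination
- `mavemap.analysis` — quadrants, profiles, group tests, ΔΔG, depletion,
  phenotypes
- `mavemap.calibrate` / `mavemap.kde` — balanced PR, AUBPRC/R80BP, LLRp,
  evidence strengths
- `mavemap.io` / `mavemap.cli` — formats, config, command-line interface

See `docs/methods.md` for the modeling choices and their rationale.
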