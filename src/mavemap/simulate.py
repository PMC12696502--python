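"""Synthetic multiplexed-screen generator.

Produces ground-truth variant effects and per-tile sequencing count tables
for pre-selection, post-selection, and wild-type-control conditions, under
either a growth-based (competitive fitness) or gate-based (FACS sort)
selection model, plus synthetic clinical reference labels. The generator
emulates the study conditions of a TileSeq/VAMP-seq screen of a SOD1-sized
ORF: bimodal missense effects anchored by nonsense ≈ 0 and synonymous ≈ 1,
clone complexity of ≥50 independent clones per variant, per-cell codon
substitution loads of ~0.64 (growth) or ~0.83 (gate), and a wild-type
control capturing base-call error background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .variants import OrfSequence, VariantSpace, enumerate_variant_space

__all__ = [
    "SimulationConfig",
    "simulate_true_effects",
    "simulate_screen",
    "simulate_reference_set",
    "synthetic_orf",
    "multi_mutant_fraction",
]

CONDITIONS = ("pre", "post", "wt_control")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic screen.

    depth is reads per (tile, condition, replicate), scaled down from the
    >1.3e6 reads/tile of a production screen; theta is the fraction of
    missense variants drawn from the deleterious mixture component;
    selection_fold is the post/pre enrichment fold between a full-effect
    (score 1) and null (score 0) variant under growth selection;
    error_rate is the per-variant wild-type-control background frequency
    for substitutions reachable by a single base miscall.
    """

    seed: int = 0
    n_replicates: int = 2
    depth: int = 200_000
    theta: float = 0.3
    mode_deleterious: float = 0.0
    mode_neutral: float = 1.0
    sd_deleterious: float = 0.15
    sd_neutral: float = 0.15
    mutation_load: float | None = None  # defaults per assay: 0.64 growth, 0.83 gate
    clones_per_variant: int = 50
    selection_fold: float = 32.0
    error_rate: float = 2e-6
    gate_midpoint: float = 0.5
    gate_slope: float = 8.0
    effect_support: tuple[float, float] = (-0.5, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0,1], got {self.theta}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.clones_per_variant < 1:
            raise ValueError("clones_per_variant must be >= 1")
        for name in ("sd_deleterious", "sd_neutral", "selection_fold",
                     "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.effect_support
        if lo >= hi:
            raise ValueError("effect_support must be an increasing interval")

    def resolved_load(self, assay: str) -> float:
        if self.mutation_load is not None:
            return self.mutation_load
        return 0.64 if assay == "growth" else 0.83

    def to_dict(self) -> dict:
        return asdict(self)


def synthetic_orf(n_codons: int = 154, seed: int = 7) -> OrfSequence:
    """A random synthetic ORF of the given protein length (SOD1-sized default).

    This is a synthetic stand-in sequence: ATG start, no internal stops, and
    a trailing stop codon; it is not any natural gene.
    """
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    bases = np.array(list("ACGT"))
    while len(codons) < n_codons:
        c = "".join(rng.choice(bases, 3))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return OrfSequence("".join(codons))


def multi_mutant_fraction(lam: float) -> float:
    """Fraction of mutant clones carrying >1 codon substitution.

    Diagnostic for a Poisson per-cell mutation load: P(N >= 2 | N >= 1).
    """
    if lam <= 0:
        return 0.0
    p_ge1 = 1.0 - math.exp(-lam)
    p_ge2 = p_ge1 - lam * math.exp(-lam)
    return p_ge2 / p_ge1


def simulate_true_effects(space: VariantSpace, cfg: SimulationConfig) -> pd.DataFrame:
    """Draw ground-truth effects per variant on the 0 = null / 1 = WT scale.

    Synonymous variants are exactly 1, nonsense exactly 0; missense effects
    come from a two-component normal mixture (deleterious component with
    probability theta), clipped to ``cfg.effect_support`` so that mildly
    above-WT ("hyper") scores exist while the mixture stays proper.
    """
    rng = np.random.default_rng(cfg.seed)
    tab = space.table.copy()
    n = len(tab)
    is_mis = (tab["klass"] == "missense").to_numpy()
    deleterious = rng.random(n) < cfg.theta
    eff = np.where(
        deleterious,
        rng.normal(cfg.mode_deleterious, cfg.sd_deleterious, n),
        rng.normal(cfg.mode_neutral, cfg.sd_neutral, n),
    )
    eff = np.clip(eff, *cfg.effect_support)
    tab["true_score"] = np.where(
        is_mis, eff,
        np.where(tab["klass"] == "nonsense", 0.0, 1.0),
    )
    tab["true_deleterious"] = is_mis & deleterious
    return tab


def _gate_prob(score: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-cfg.gate_slope * (score - cfg.gate_midpoint)))


def simulate_screen(effects: pd.DataFrame, cfg: SimulationConfig,
                    assay: str = "growth") -> pd.DataFrame:
    """Sample a counts bundle from the generative screen model.

    Per tile and replicate: pre-selection variant frequencies follow
    clone-multiplicity dispersion (log-normal weights whose coefficient of
    variation shrinks as 1/sqrt(clones_per_variant)) summing to the tile's
    mutant read fraction (Poisson load apportioned by codon count); the
    post-selection expectation multiplies pre frequencies by ``B**score``
    (growth) or by a logistic gate-pass probability (gate); wild-type-control
    frequencies are the error background alone, which is also added to pre
    and post. Observed counts are one multinomial draw of size ``depth`` per
    (tile, condition, replicate); the wild-type read share is the unreported
    remainder, so variant counts sum to <= depth.

    Returns a tidy counts table: tile, condition, replicate, variant, count,
    depth.
    """
    if assay not in ("growth", "gate"):
        raise ValueError(f"unknown assay {assay!r}: expected 'growth' or 'gate'")
    if cfg.depth < 1:
        raise ValueError("depth must be >= 1")
    required = {"variant", "tile", "true_score", "snv_accessible"}
    missing = required - set(effects.columns)
    if missing:
        raise ValueError(f"effects table missing columns: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    lam = cfg.resolved_load(assay)
    total_codons = effects["position"].nunique()
    cv = 1.0 / math.sqrt(cfg.clones_per_variant)
    sigma = math.sqrt(math.log1p(cv * cv))

    out = []
    for tile, group in effects.groupby("tile", sort=True):
        n_v = len(group)
        codons_in_tile = group["position"].nunique()
        mutant_frac = min(0.9, lam * codons_in_tile / total_codons)
        score = group["true_score"].to_numpy()
        err = np.where(group["snv_accessible"].to_numpy(), cfg.error_rate, 0.0)

        for rep in range(1, cfg.n_replicates + 1):
            clone_w = rng.lognormal(mean=0.0, sigma=sigma, size=n_v)
            pre = mutant_frac * clone_w / clone_w.sum()
            wt_pre = 1.0 - mutant_frac

            if assay == "growth":
                sel = np.power(cfg.selection_fold, score)
                wt_sel = cfg.selection_fold  # WT has score 1
            else:
                sel = _gate_prob(score, cfg)
                wt_sel = float(_gate_prob(np.array([1.0]), cfg)[0])
            post_w = pre * sel
            wt_post = wt_pre * wt_sel
            post_total = post_w.sum() + wt_post
            post = post_w / post_total

            expectations = {
                "pre": (pre + err, wt_pre),
                "post": (post + err, wt_post / post_total),
                "wt_control": (err, 1.0),
            }
            for cond, (freq, wt_share) in expectations.items():
                probs = np.append(freq, max(wt_share, 0.0))
                probs = probs / probs.sum()
                draw = rng.multinomial(cfg.depth, probs)
                counts = draw[:-1]  # last slot is WT reads
                out.append(pd.DataFrame({
                    "tile": tile,
                    "condition": cond,
                    "replicate": rep,
                    "variant": group["variant"].to_numpy(),
                    "count": counts,
                    "depth": cfg.depth,
                }))
    return pd.concat(out, ignore_index=True)


def simulate_reference_set(effects: pd.DataFrame, n_pos: int, n_neg: int,
                           overlap: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Draw disjoint synthetic P/LP-like and B/PB-like reference labels.

    Positives sample from the low-true-effect half of missense variants and
    negatives from the high half; with probability ``overlap`` a pick is
    drawn from the full pool instead, so overlap = 0 gives perfect
    separability and overlap = 1 labels independent of effect.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0,1]")
    mis = effects[effects["klass"] == "missense"]
    mis = mis.sort_values("true_score", kind="mergesort").reset_index(drop=True)
    n = len(mis)
    if n_pos + n_neg > n:
        raise ValueError(
            f"requested {n_pos}+{n_neg} labels but only {n} missense variants")
    rng = np.random.default_rng(seed)
    half = n // 2
    lower = list(range(half))
    upper = list(range(half, n))
    taken: set[int] = set()

    def pick(pool: list[int]) -> int:
        candidates = [i for i in pool if i not in taken]
        if not candidates:
            raise ValueError("reference pool exhausted")
        i = int(rng.choice(candidates))
        taken.add(i)
        return i

    rows = []
    for _ in range(n_pos):
        pool = lower if rng.random() >= overlap else list(range(n))
        i = pick(pool)
        rows.append((mis.loc[i, "variant"], "P", mis.loc[i, "true_score"]))
    for _ in range(n_neg):
        pool = upper if rng.random() >= overlap else list(range(n))
        i = pick(pool)
        rows.append((mis.loc[i, "variant"], "B", mis.loc[i, "true_score"]))
    return pd.DataFrame(rows, columns=["variant", "label", "true_score"]).assign(
        source="synthetic")
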