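"""TileSeq-style scoring: counts to a rescaled variant-effect map.

Stages, composed in order by :func:`score_pipeline` / :class:`TileSeqScorer`:

1. frequencies (reads per million) per (variant, condition, replicate);
2. pre-selection count and WT-percentile filters, well-measured flag;
3. WT-error-corrected log2 enrichment ratios with delta-method variance;
4. rescaling so the per-replicate nonsense median is 0 and the synonymous
   median is 1;
5. regularization of standard errors against the pre-frequency trend;
6. inverse-variance-weighted replicate combination with
   Welch-Satterthwaite degrees of freedom.

Scores land on the 0 = null / 1 = wild-type-like scale used throughout the
downstream analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variants import parse_variant

__all__ = [
    "ScoringConfig",
    "TileSeqScorer",
    "ScreenSeparationError",
    "compute_frequencies",
    "apply_filters",
    "enrichment_scores",
    "rescale_scores",
    "regularize_errors",
    "combine_replicates",
    "score_pipeline",
]

log = logging.getLogger(__name__)

LN2_SQ_INV = 1.0 / math.log(2.0) ** 2


class ScreenSeparationError(RuntimeError):
    """Raised when nonsense and synonymous anchors do not separate."""


@dataclass
class ScoringConfig:
    """Tunable thresholds of the scoring pipeline."""

    min_count: int = 10          # minimum pre-selection reads per replicate
    wt_percentile: float = 90.0  # pre freq must exceed this WT-control percentile
    min_pre_ppm: float = 10.0    # well-measured requires >= this pre frequency
    min_anchors: int = 10        # measurable nonsense/synonymous needed to rescale
    prior_df: float = 2.0        # pseudo-replicates behind the error trend prior
    min_fit_variants: int = 30   # below this, skip error regularization
    exclude_start_codon: bool = True
    exclude_terminal_stop: bool = True


def _variant_klass(series: pd.Series) -> pd.Series:
    return series.map(lambda v: parse_variant(v).klass)


def compute_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million frequencies, keeping raw count and depth alongside."""
    required = {"tile", "condition", "replicate", "variant", "count", "depth"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    bad = counts[counts["depth"] <= 0]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"zero depth at tile={row['tile']}, condition={row['condition']}, "
            f"replicate={row['replicate']}")
    freqs = counts.copy()
    freqs["freq"] = freqs["count"] / freqs["depth"] * 1e6
    return freqs


def _wt_summary(freqs: pd.DataFrame) -> pd.DataFrame:
    """Mean WT-control frequency per variant (pooled over WT replicates)."""
    wt = freqs[freqs["condition"] == "wt_control"]
    if wt.empty:
        raise ValueError("no wt_control condition in counts bundle")
    return (wt.groupby(["tile", "variant"], as_index=False)
              .agg(wt_freq=("freq", "mean"), wt_n=("freq", "size"),
                   wt_depth=("depth", "mean")))


def apply_filters(freqs: pd.DataFrame, cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Pivot to one row per (variant, replicate) and apply count/WT filters.

    A variant is excluded in a replicate if its pre-selection count is below
    ``min_count`` or its pre-selection frequency does not exceed the
    ``wt_percentile``-th percentile of the WT-control frequencies of its tile
    (pooled across variants). ``well_measured`` additionally requires a
    pre-selection frequency of at least ``min_pre_ppm`` reads per million.
    """
    cfg = cfg or ScoringConfig()
    wt = _wt_summary(freqs)
    wide = (freqs[freqs["condition"].isin(["pre", "post"])]
            .pivot_table(index=["tile", "variant", "replicate"],
                         columns="condition",
                         values=["count", "freq", "depth"],
                         aggfunc="first"))
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index().merge(wt, on=["tile", "variant"], how="left")
    wide["wt_freq"] = wide["wt_freq"].fillna(0.0)

    # per-tile WT percentile threshold, pooled over all variants of the tile
    thresholds = (freqs[freqs["condition"] == "wt_control"]
                  .groupby("tile")["freq"]
                  .quantile(cfg.wt_percentile / 100.0)
                  .rename("wt_threshold"))
    wide = wide.merge(thresholds, on="tile", how="left")
    wide["wt_threshold"] = wide["wt_threshold"].fillna(0.0)

    wide["excluded"] = (wide["count_pre"].fillna(0) < cfg.min_count) | (
        wide["freq_pre"].fillna(0.0) <= wide["wt_threshold"])
    # degenerate all-zero WT control: percentile rule excludes nothing
    wide.loc[wide["wt_threshold"] <= 0.0, "excluded"] = (
        wide.loc[wide["wt_threshold"] <= 0.0, "count_pre"].fillna(0) < cfg.min_count)
    wide["well_measured"] = (~wide["excluded"]) & (
        wide["freq_pre"].fillna(0.0) >= cfg.min_pre_ppm)
    return wide


def enrichment_scores(filtered: pd.DataFrame) -> pd.DataFrame:
    """Error-corrected log2 enrichment ratios with delta-method variance.

    Corrected frequencies subtract the mean WT-control frequency from both
    conditions. A non-positive corrected pre frequency makes the variant
    unmeasurable in that replicate (pre absence is uninformative); a
    non-positive corrected post frequency is floored at a half-read
    pseudo-frequency (post depletion to zero is informative). Poisson count
    noise, Var(f) = f * 1e6 / D in ppm^2, propagates through the subtraction
    and the log via the delta method.
    """
    out = filtered.copy()
    out["f_pre_corr"] = out["freq_pre"] - out["wt_freq"]
    out["f_post_corr"] = out["freq_post"] - out["wt_freq"]

    floor_post = 0.5 / out["depth_post"] * 1e6
    out["floored"] = out["f_post_corr"] <= 0.0
    out["f_post_corr"] = out["f_post_corr"].where(~out["floored"], floor_post)
    out["unmeasurable"] = out["excluded"] | (out["f_pre_corr"] <= 0.0) | \
        out["freq_post"].isna() | out["freq_pre"].isna()

    # Poisson variance of each frequency term, in ppm^2; WT variance shrinks
    # with the number of pooled WT replicates
    var_pre = out["freq_pre"] * 1e6 / out["depth_pre"]
    var_post = out["freq_post"] * 1e6 / out["depth_post"]
    var_wt = out["wt_freq"] * 1e6 / out["wt_depth"].replace(0, np.nan) / \
        out["wt_n"].replace(0, np.nan)
    var_wt = var_wt.fillna(0.0)
    var_pre_corr = var_pre + var_wt
    var_post_corr = np.maximum(var_post + var_wt,
                               (floor_post) * 1e6 / out["depth_post"])

    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_phi"] = np.log2(out["f_post_corr"] / out["f_pre_corr"])
        var_log = LN2_SQ_INV * (var_post_corr / out["f_post_corr"] ** 2 +
                                var_pre_corr / out["f_pre_corr"] ** 2)
    out["se_log_phi"] = np.sqrt(var_log)
    out.loc[out["unmeasurable"], ["log_phi", "se_log_phi"]] = np.nan
    out["df"] = 1.0
    return out


def rescale_scores(enriched: pd.DataFrame, cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Rescale log-enrichments so nonsense medians 0 and synonymous 1.

    Within each replicate, s = (log_phi - med_nonsense) / (med_synonymous -
    med_nonsense); standard errors scale by the same positive factor. Raises
    :class:`ScreenSeparationError` when the synonymous median does not exceed
    the nonsense median (a failed screen), and ``ValueError`` when fewer than
    ``min_anchors`` measurable anchors of either class exist.
    """
    cfg = cfg or ScoringConfig()
    out = enriched.copy()
    if "klass" not in out.columns:
        out["klass"] = _variant_klass(out["variant"])
    out["score"] = np.nan
    out["se"] = np.nan
    anchors = {}
    for rep, grp in out.groupby("replicate"):
        measurable = grp[~grp["unmeasurable"]]
        non = measurable.loc[measurable["klass"] == "nonsense", "log_phi"]
        syn = measurable.loc[measurable["klass"] == "synonymous", "log_phi"]
        if len(non) < cfg.min_anchors or len(syn) < cfg.min_anchors:
            raise ValueError(
                f"replicate {rep}: need >= {cfg.min_anchors} measurable "
                f"nonsense and synonymous anchors, have {len(non)}/{len(syn)}")
        med_non, med_syn = float(non.median()), float(syn.median())
        if med_syn <= med_non:
            raise ScreenSeparationError(
                f"replicate {rep}: no selection separation "
                f"(median_syn={med_syn:.3g} <= median_non={med_non:.3g})")
        scale = med_syn - med_non
        idx = grp.index
        out.loc[idx, "score"] = (grp["log_phi"] - med_non) / scale
        out.loc[idx, "se"] = grp["se_log_phi"] / scale
        anchors[rep] = (med_non, med_syn)
    out.attrs["anchors"] = anchors
    return out


def _lad_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-absolute-deviations line y ~ a + b x (median regression)."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    res = sm.QuantReg(y, X).fit(q=0.5)
    return float(res.params[0]), float(res.params[1])


def regularize_errors(rescaled: pd.DataFrame, cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Shrink per-replicate standard errors toward a pre-frequency trend.

    Fits log10(se) ~ a + b * log10(f_pre) by least absolute deviations over
    measurable variants of each replicate, then combines model and empirical
    variances with ``prior_df`` pseudo-observations behind the model:
    var_reg = (m * se_model^2 + df * se_emp^2) / (m + df), df -> m + df.
    With too few variants for a stable fit the empirical errors pass through
    unchanged (with a warning).
    """
    cfg = cfg or ScoringConfig()
    out = rescaled.copy()
    out["se_raw"] = out["se"]
    for rep, grp in out.groupby("replicate"):
        fit_ok = (~grp["unmeasurable"]) & (grp["se"] > 0) & (grp["freq_pre"] > 0)
        pts = grp[fit_ok]
        if len(pts) < cfg.min_fit_variants:
            log.warning("replicate %s: only %d variants for error trend fit; "
                        "keeping unregularized errors", rep, len(pts))
            continue
        a, b = _lad_fit(np.log10(pts["freq_pre"].to_numpy()),
                        np.log10(pts["se"].to_numpy()))
        # shrinkage applies to every measurable variant, including se == 0
        # artifacts from identical replicate draws
        apply_ok = (~grp["unmeasurable"]) & grp["se"].notna() & \
            (grp["freq_pre"] > 0)
        idx = grp.index[apply_ok]
        se_model = 10.0 ** (a + b * np.log10(grp.loc[idx, "freq_pre"]))
        m, df = cfg.prior_df, grp.loc[idx, "df"]
        var_reg = (m * se_model ** 2 + df * grp.loc[idx, "se"] ** 2) / (m + df)
        out.loc[idx, "se"] = np.sqrt(var_reg)
        out.loc[idx, "df"] = m + df
        out.attrs.setdefault("error_fit", {})[rep] = (a, b)
    return out


def combine_replicates(rescaled: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance-weighted average of replicate scores per variant.

    Weights w_r = 1/se_r^2 give s = sum(w s)/sum(w), se = sqrt(1/sum(w)),
    and degrees of freedom follow Welch-Satterthwaite. Variants with a
    single measurable replicate pass se and df through unchanged; variants
    with none are absent from the map.
    """
    rows = []
    for (variant,), grp in rescaled.groupby(["variant"]):
        meas = grp[(~grp["unmeasurable"]) & grp["se"].notna() & (grp["se"] > 0)]
        if meas.empty:
            continue
        klass = grp["klass"].iloc[0] if "klass" in grp else None
        if len(meas) == 1:
            r = meas.iloc[0]
            rows.append((variant, klass, float(r["score"]), float(r["se"]),
                         float(r["df"]), 1, bool(r["well_measured"])))
            continue
        w = 1.0 / meas["se"] ** 2
        score = float((w * meas["score"]).sum() / w.sum())
        se = float(np.sqrt(1.0 / w.sum()))
        df = float(w.sum() ** 2 / ((w ** 2 / meas["df"]).sum()))
        rows.append((variant, klass, score, se, df, len(meas),
                     bool(meas["well_measured"].all())))
    out = pd.DataFrame(rows, columns=["variant", "klass", "score", "se", "df",
                                      "n_replicates", "well_measured"])
    return out.sort_values("variant", kind="mergesort").reset_index(drop=True)


def score_pipeline(counts: pd.DataFrame, cfg: ScoringConfig | None = None,
                   variant_info: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full deterministic composition of the scoring stages.

    ``variant_info`` may supply ``variant``, ``klass`` (and optionally
    ``start_codon`` / ``terminal_stop`` flags); otherwise the class is parsed
    from the variant notation. Returns the combined variant-effect map with
    per-stage counts logged.
    """
    cfg = cfg or ScoringConfig()
    freqs = compute_frequencies(counts)
    filtered = apply_filters(freqs, cfg)
    log.info("filters: %d/%d (variant, replicate) rows retained",
             int((~filtered["excluded"]).sum()), len(filtered))

    if variant_info is not None:
        info = variant_info.drop_duplicates("variant").set_index("variant")
        filtered["klass"] = filtered["variant"].map(info["klass"])
        for flag in ("start_codon", "terminal_stop"):
            if flag in info.columns:
                drop = filtered["variant"].map(info[flag]).fillna(False)
                if (flag == "start_codon" and cfg.exclude_start_codon) or \
                   (flag == "terminal_stop" and cfg.exclude_terminal_stop):
                    filtered = filtered[~drop.astype(bool)]
    else:
        filtered["klass"] = _variant_klass(filtered["variant"])

    enriched = enrichment_scores(filtered)
    log.info("enrichment: %d measurable rows", int((~enriched["unmeasurable"]).sum()))
    rescaled = rescale_scores(enriched, cfg)
    regularized = regularize_errors(rescaled, cfg)
    effect_map = combine_replicates(regularized)
    effect_map.attrs["anchors"] = rescaled.attrs.get("anchors", {})
    effect_map.attrs["error_fit"] = regularized.attrs.get("error_fit", {})
    log.info("map: %d variants scored", len(effect_map))
    return effect_map


class TileSeqScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from a counts bundle to a variant-effect map.

    Parameters mirror :class:`ScoringConfig`. ``fit`` computes the map and
    stores it as ``effect_map_`` (with ``anchors_`` and ``error_fit_``);
    ``transform`` returns the map for the given counts table.

    Examples
    --------
    >>> scorer = TileSeqScorer(min_count=10)
    >>> vmap = scorer.fit_transform(counts)           # doctest: +SKIP
    """

    def __init__(self, min_count: int = 10, wt_percentile: float = 90.0,
                 min_pre_ppm: float = 10.0, min_anchors: int = 10,
                 prior_df: float = 2.0, min_fit_variants: int = 30,
                 exclude_start_codon: bool = True,
                 exclude_terminal_stop: bool = True):
        self.min_count = min_count
        self.wt_percentile = wt_percentile
        self.min_pre_ppm = min_pre_ppm
        self.min_anchors = min_anchors
        self.prior_df = prior_df
        self.min_fit_variants = min_fit_variants
        self.exclude_start_codon = exclude_start_codon
        self.exclude_terminal_stop = exclude_terminal_stop

    def _config(self) -> ScoringConfig:
        return ScoringConfig(
            min_count=self.min_count, wt_percentile=self.wt_percentile,
            min_pre_ppm=self.min_pre_ppm, min_anchors=self.min_anchors,
            prior_df=self.prior_df, min_fit_variants=self.min_fit_variants,
            exclude_start_codon=self.exclude_start_codon,
            exclude_terminal_stop=self.exclude_terminal_stop)

    def fit(self, X: pd.DataFrame, y=None, variant_info: pd.DataFrame | None = None):
        effect_map = score_pipeline(X, self._config(), variant_info)
        self.effect_map_ = effect_map
        self.anchors_ = effect_map.attrs.get("anchors", {})
        self.error_fit_ = effect_map.attrs.get("error_fit", {})
        return self

    def transform(self, X: pd.DataFrame, variant_info: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
        return score_pipeline(X, self._config(), variant_info)

    def fit_transform(self, X: pd.DataFrame, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y, **fit_params).effect_map_
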