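"""Biological analyses of single and paired variant-effect maps.

Joint activity/abundance quadrant classification, positional and
substitution profiles, annotation-group contrasts (Mann-Whitney U),
thermostability (ddG) concordance with moving windows, population
depletion odds ratios, and genotype-phenotype correlation.

A variant is deleterious in a map iff its score is strictly below the
threshold (default 0.5, the midpoint between the nonsense and synonymous
anchors at 0 and 1).
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import parse_variant

__all__ = [
    "QUADRANTS",
    "classify_quadrants",
    "dominant_quadrant_by_position",
    "positional_profile",
    "substitution_profile",
    "compare_feature_groups",
    "burial_class",
    "stability_class",
    "ddg_concordance",
    "population_depletion_odds",
    "weighted_phenotype_average",
    "phenotype_association",
]

#: quadrant labels with their conventional map colors
QUADRANTS = {
    "both_deleterious": "blue",
    "both_neutral": "white",
    "activity_only": "purple",
    "abundance_only": "teal",
}

DELETERIOUS_THRESHOLD = 0.5


def _positions(variants: pd.Series) -> pd.Series:
    return variants.map(lambda v: parse_variant(v).position)


def _well_measured(effect_map: pd.DataFrame) -> pd.DataFrame:
    out = effect_map
    if "well_measured" in out.columns:
        out = out[out["well_measured"].astype(bool)]
    return out


def classify_quadrants(activity: pd.DataFrame, abundance: pd.DataFrame,
                       threshold: float = DELETERIOUS_THRESHOLD) -> pd.DataFrame:
    """Joint deleteriousness class for variants measured in both maps.

    Only missense variants well measured in both maps are classified.
    Deleterious in a map iff score < threshold (strict). Summary
    percentages over the classified set are stored in
    ``.attrs['percentages']``.
    """
    act = _well_measured(activity)
    abu = _well_measured(abundance)
    if "klass" in act.columns:
        act = act[act["klass"] == "missense"]
    if "klass" in abu.columns:
        abu = abu[abu["klass"] == "missense"]
    joined = act[["variant", "score"]].merge(
        abu[["variant", "score"]], on="variant",
        suffixes=("_activity", "_abundance"))
    if joined.empty:
        raise ValueError("no shared well-measured variants between maps")
    act_del = joined["score_activity"] < threshold
    abu_del = joined["score_abundance"] < threshold
    quadrant = np.select(
        [act_del & abu_del, act_del & ~abu_del, ~act_del & abu_del],
        ["both_deleterious", "activity_only", "abundance_only"],
        default="both_neutral")
    joined["quadrant"] = quadrant
    joined["position"] = _positions(joined["variant"])
    pct = (joined["quadrant"].value_counts(normalize=True) * 100.0)
    joined.attrs["percentages"] = {q: float(pct.get(q, 0.0)) for q in QUADRANTS}
    joined.attrs["threshold"] = threshold
    return joined


def dominant_quadrant_by_position(quadrants: pd.DataFrame) -> pd.Series:
    """Strict-plurality quadrant label per position; ties give None (gray)."""
    out = {}
    for pos, grp in quadrants.groupby("position"):
        counts = Counter(grp["quadrant"])
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[pos] = None
        else:
            out[pos] = ranked[0][0]
    return pd.Series(out, name="dominant_quadrant").rename_axis("position")


def positional_profile(effect_map: pd.DataFrame,
                       stat: str = "median") -> pd.DataFrame:
    """Per-position aggregate of measured missense scores.

    ``stat`` is ``median`` (structure profiles) or ``mean`` (phenotype
    comparison). Positions with no measured missense substitution are
    absent from the result.
    """
    if stat not in ("median", "mean"):
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")
    m = _well_measured(effect_map)
    if "klass" in m.columns:
        m = m[m["klass"] == "missense"]
    if m.empty:
        raise ValueError("no measured missense variants in map")
    m = m.assign(position=_positions(m["variant"]))
    prof = (m.groupby("position")["score"]
             .agg(value=stat, n="size")
             .reset_index())
    prof.attrs["stat"] = stat
    return prof


def substitution_profile(effect_map: pd.DataFrame) -> pd.DataFrame:
    """Median score per 'to' and 'from' amino acid over missense variants.

    Returns one row per amino acid with ``to_median``/``to_n`` (alt residue)
    and ``from_median``/``from_n`` (reference residue); a residue absent
    from the reference leaves the 'from' entry undefined (NaN, n = 0).
    """
    m = _well_measured(effect_map)
    if "klass" in m.columns:
        m = m[m["klass"] == "missense"]
    if m.empty:
        raise ValueError("no measured missense variants in map")
    parsed = m["variant"].map(parse_variant)
    m = m.assign(ref_aa=[p.ref_aa for p in parsed],
                 alt_aa=[p.alt_aa for p in parsed])
    from .variants import AA_ORDER
    to_med = m.groupby("alt_aa")["score"].agg(["median", "size"])
    from_med = m.groupby("ref_aa")["score"].agg(["median", "size"])
    rows = []
    for aa in AA_ORDER:
        rows.append({
            "aa": aa,
            "to_median": to_med["median"].get(aa, np.nan),
            "to_n": int(to_med["size"].get(aa, 0)),
            "from_median": from_med["median"].get(aa, np.nan),
            "from_n": int(from_med["size"].get(aa, 0)),
        })
    return pd.DataFrame(rows)


def rank_correlation(vec_a: pd.Series | np.ndarray, vec_b: pd.Series | np.ndarray,
                     method: str = "spearman") -> tuple[float, float]:
    """Correlation between two aligned vectors, NaN pairs dropped."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    if method == "spearman":
        r, p = stats.spearmanr(a[ok], b[ok])
    elif method == "pearson":
        r, p = stats.pearsonr(a[ok], b[ok])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def compare_feature_groups(profile: pd.DataFrame, groups: dict[str, list[int]],
                           allow_overlap: bool = False,
                           exact_max_n: int = 8) -> pd.DataFrame:
    """Pairwise Mann-Whitney U contrasts between positional feature groups.

    ``groups`` maps a feature name to its positions; values come from the
    positional profile. Exact two-sided p-values are used when both groups
    have at most ``exact_max_n`` members, the normal approximation
    otherwise; p-values are Benjamini-Hochberg adjusted across pairs.
    """
    names = list(groups)
    if not allow_overlap:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shared = set(groups[a]) & set(groups[b])
                if shared:
                    raise ValueError(
                        f"groups {a!r} and {b!r} overlap at positions "
                        f"{sorted(shared)[:5]}; pass allow_overlap=True")
    prof = profile.set_index("position")["value"]
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = prof.reindex(groups[a]).dropna().to_numpy()
            vb = prof.reindex(groups[b]).dropna().to_numpy()
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(f"group pair ({a}, {b}) has <2 scored positions")
            method = ("exact" if len(va) <= exact_max_n and len(vb) <= exact_max_n
                      else "asymptotic")
            res = stats.mannwhitneyu(va, vb, alternative="two-sided",
                                     method=method)
            rows.append({
                "group_a": a, "group_b": b,
                "n_a": len(va), "n_b": len(vb),
                "delta_median": float(np.median(va) - np.median(vb)),
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "method": method,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def burial_class(relative_exposure: float) -> str:
    """Exposed above 35% relative solvent exposure, buried below 20%."""
    if relative_exposure > 35.0:
        return "exposed"
    if relative_exposure < 20.0:
        return "buried"
    return "intermediate"


def stability_class(ddg: float) -> str:
    """DDGun3D sign convention: negative = destabilizing.

    Stabilizing-or-neutral iff ddG > -0.1; destabilizing iff ddG < -0.5.
    """
    if ddg > -0.1:
        return "stabilizing_or_neutral"
    if ddg < -0.5:
        return "destabilizing"
    return "intermediate"


def ddg_concordance(effect_map: pd.DataFrame, ddg: pd.DataFrame,
                    window_size: int = 10,
                    threshold: float = DELETERIOUS_THRESHOLD) -> dict:
    """Moving-window comparison of map scores with predicted stability.

    Returns a dict with ``windows`` (per-window mean score and mean ddG,
    step 1), ``stable_but_inactive`` (variants with score < threshold whose
    ddG is stabilizing-or-neutral, i.e. functional impact not explained by
    stability), and ``correlation`` (Spearman rho, p over shared variants).
    """
    shared = _well_measured(effect_map)[["variant", "score"]].merge(
        ddg[["variant", "ddg"]], on="variant")
    if shared.empty:
        raise ValueError("no variants shared between map and ddG table")
    shared["position"] = _positions(shared["variant"])
    n_pos = int(shared["position"].max())
    if window_size > n_pos:
        raise ValueError(f"window_size {window_size} exceeds protein span {n_pos}")

    per_pos = shared.groupby("position")[["score", "ddg"]].mean()
    rows = []
    for start in range(1, n_pos - window_size + 2):
        stop = start + window_size
        block = per_pos.reindex(range(start, stop)).dropna()
        if block.empty:
            continue
        rows.append({
            "window_start": start, "window_stop": stop,
            "mean_score": float(block["score"].mean()),
            "mean_ddg": float(block["ddg"].mean()),
            "n_positions": len(block),
        })
    sbi = shared[(shared["score"] < threshold) &
                 (shared["ddg"].map(stability_class) == "stabilizing_or_neutral")]
    rho, p = stats.spearmanr(shared["score"], shared["ddg"])
    return {
        "windows": pd.DataFrame(rows),
        "stable_but_inactive": sbi["variant"].tolist(),
        "correlation": (float(rho), float(p)),
    }


def population_depletion_odds(map_classes: pd.Series,
                              presence: pd.Series) -> dict:
    """Depletion odds ratio of damaging variants from a population table.

    ``map_classes`` maps variant -> {damaging, neutral} and ``presence``
    maps variant -> {present, absent} in the population database. The 2x2
    table is [[damaging&present, damaging&absent], [neutral&present,
    neutral&absent]]; the natural-log odds ratio uses a Haldane-Anscombe
    0.5 correction when any cell is zero, and the two-sided Fisher exact
    p-value is computed on the uncorrected table.
    """
    joined = pd.DataFrame({"klass": map_classes, "presence": presence}).dropna()
    if joined.empty:
        raise ValueError("empty damaging/presence table")
    a = int(((joined["klass"] == "damaging") & (joined["presence"] == "present")).sum())
    b = int(((joined["klass"] == "damaging") & (joined["presence"] == "absent")).sum())
    c = int(((joined["klass"] == "neutral") & (joined["presence"] == "present")).sum())
    d = int(((joined["klass"] == "neutral") & (joined["presence"] == "absent")).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    corrected = table + 0.5 if (table == 0).any() else table
    odds = (corrected[0, 0] * corrected[1, 1]) / (corrected[0, 1] * corrected[1, 0])
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return {
        "table": table.astype(int),
        "odds_ratio": float(odds),
        "log_odds_ratio": float(np.log(odds)),
        "fisher_p": float(p),
        "haldane_corrected": bool((table == 0).any()),
    }


def weighted_phenotype_average(values, weights) -> float:
    """Sample-size-weighted average of per-study phenotype values."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or w.sum() <= 0:
        raise ValueError("no values / nonpositive total weight")
    return float((v * w).sum() / w.sum())


def phenotype_association(profile: pd.DataFrame, phenotypes: pd.DataFrame,
                          method: str = "spearman",
                          min_shared: int = 3) -> pd.DataFrame:
    """Correlate positional mean scores with aggregated phenotype values.

    ``phenotypes`` is long-form with columns position, phenotype, value,
    sample_size (one row per study); per-study values aggregate by
    sample-size-weighted average before correlating against the profile.
    Phenotypes with fewer than ``min_shared`` shared positions are skipped
    with a warning; p-values are BH-adjusted across phenotypes.
    """
    prof = profile.set_index("position")["value"]
    rows = []
    for pheno, grp in phenotypes.groupby("phenotype"):
        agg = grp.groupby("position").apply(
            lambda g: weighted_phenotype_average(g["value"], g["sample_size"]),
            include_groups=False)
        shared = agg.index.intersection(prof.index)
        if len(shared) < min_shared:
            warnings.warn(f"phenotype {pheno!r}: only {len(shared)} shared "
                          f"positions; skipped")
            continue
        r, p = rank_correlation(prof.loc[shared], agg.loc[shared], method)
        rows.append({"phenotype": pheno, "n": len(shared),
                     "correlation": r, "p_value": p, "method": method})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
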