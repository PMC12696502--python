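"""Clinical benchmarking and LLR calibration of variant-effect maps.

Evaluates a map against pathogenic/benign reference sets with balanced
precision-recall curves (precision re-weighted to a 50/50 prior), their
area (AUBPRC) and the recall at 80% balanced precision (R80BP); transforms
scores into log10 likelihood ratios of pathogenicity (LLRp) via separate
Epanechnikov kernel density estimates of the pathogenic and benign score
distributions; and assigns ACMG/AMP-style functional-evidence strengths
from the Tavtigian combined-odds ladder.

Score polarity is lower = more pathogenic throughout: both assays behind
the maps are loss-of-function signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .kde import EpanechnikovKDE

__all__ = [
    "POSITIVE_LABELS",
    "NEGATIVE_LABELS",
    "assemble_labeled_scores",
    "balanced_precision_recall",
    "aubprc",
    "r80bp",
    "compute_llr",
    "assign_evidence",
    "evidence_thresholds",
    "LlrCalibrator",
]

#: clinical labels mapped to the positive (pathogenic) reference class
POSITIVE_LABELS = {"P", "LP", "P/LP", "positive"}
#: labels mapped to the negative (benign / proxy-benign) class
NEGATIVE_LABELS = {"B", "LB", "PB", "B/PB", "B/LB", "negative"}

EVIDENCE_LEVELS = [
    "BS3_strong", "BS3_moderate", "BS3_supporting", "indeterminate",
    "PS3_supporting", "PS3_moderate", "PS3_strong", "PS3_very_strong",
]


def _normalize_label(label: str) -> str:
    if label in POSITIVE_LABELS:
        return "positive"
    if label in NEGATIVE_LABELS:
        return "negative"
    raise ValueError(f"unknown reference label {label!r}")


def assemble_labeled_scores(effect_map: pd.DataFrame,
                            refs: pd.DataFrame) -> pd.DataFrame:
    """Inner-join map scores with reference labels.

    Only reference variants having scores participate; dropped variants are
    recorded in ``.attrs['dropped']``. A variant carrying both labels is an
    error, as is fewer than two scored variants per label.
    """
    refs = refs.copy()
    refs["label"] = refs["label"].map(_normalize_label)
    per_variant = refs.groupby("variant")["label"].nunique()
    clashes = per_variant[per_variant > 1]
    if len(clashes):
        raise ValueError(
            f"variants with both labels: {sorted(clashes.index.tolist())}")
    refs = refs.drop_duplicates("variant")
    merged = refs.merge(effect_map[["variant", "score"]], on="variant",
                        how="left")
    dropped = merged.loc[merged["score"].isna(), "variant"].tolist()
    out = merged.dropna(subset=["score"]).reset_index(drop=True)
    counts = out["label"].value_counts()
    for label in ("positive", "negative"):
        if counts.get(label, 0) < 2:
            raise ValueError(
                f"fewer than 2 scored {label} reference variants "
                f"({counts.get(label, 0)}); curve undefined")
    out.attrs["dropped"] = dropped
    out.attrs["n_positive"] = int(counts["positive"])
    out.attrs["n_negative"] = int(counts["negative"])
    return out


def balanced_precision_recall(labeled: pd.DataFrame,
                              prior: float = 0.5) -> pd.DataFrame:
    """Balanced precision-recall curve over all unique score thresholds.

    A variant is called pathogenic when its score is at or below the
    threshold (low score = loss signal). At each threshold: recall = TP/P,
    FPR = FP/N, and balanced precision = recall*pi / (recall*pi +
    FPR*(1-pi)); with the balancing prior pi = 0.5 this is
    recall/(recall + FPR), i.e. precision under equal-size reference sets.
    """
    scores = labeled["score"].to_numpy(dtype=float)
    pos = (labeled["label"] == "positive").to_numpy()
    P, N = int(pos.sum()), int((~pos).sum())
    if P == 0 or N == 0:
        raise ValueError("both labels must be represented")
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    tp_cum = np.cumsum(pos[order])
    # last index of each unique score gives counts for "score <= t"
    thresholds, last = np.unique(s_sorted, return_index=True)
    last = np.append(last[1:], s_sorted.size) - 1
    tp = tp_cum[last].astype(float)
    called = last + 1.0
    fp = called - tp
    recall = tp / P
    fpr = fp / N
    denom = recall * prior + fpr * (1.0 - prior)
    with np.errstate(invalid="ignore"):
        bp = np.where(denom > 0, recall * prior / denom, np.nan)
        prec = np.where(called > 0, tp / called, np.nan)
    curve = pd.DataFrame({
        "threshold": thresholds, "recall": recall, "fpr": fpr,
        "balanced_precision": bp, "precision": prec})
    if len(thresholds) == 1:
        import warnings
        warnings.warn("single unique score: degenerate one-point curve")
    return curve


def aubprc(curve: pd.DataFrame) -> float:
    """Trapezoidal area under balanced precision over recall in [0, 1].

    The curve is extended to recall 0 with the balanced precision of the
    tightest informative threshold and to recall 1 with that of the loosest.
    """
    pts = curve.dropna(subset=["balanced_precision"])
    if len(pts) < 1:
        raise ValueError("curve has no defined balanced-precision points")
    pts = pts.sort_values(["recall", "threshold"])
    recall = pts["recall"].to_numpy(dtype=float)
    bp = pts["balanced_precision"].to_numpy(dtype=float)
    if recall[0] > 0:
        recall = np.concatenate([[0.0], recall])
        bp = np.concatenate([[bp[0]], bp])
    if recall[-1] < 1:
        recall = np.concatenate([recall, [1.0]])
        bp = np.concatenate([bp, [bp[-1]]])
    return float(np.trapezoid(bp, recall))


def r80bp(curve: pd.DataFrame, target: float = 0.80) -> float:
    """Maximum recall among thresholds with balanced precision >= target."""
    ok = curve[curve["balanced_precision"] >= target]
    if ok.empty:
        return 0.0
    return float(ok["recall"].max())


def evidence_thresholds(o_pvst: float = 350.0) -> dict[str, float]:
    """Tavtigian odds ladder on the log10 scale.

    The combined very-strong pathogenic odds O_PVSt decomposes into
    exponentially halving evidence strengths: very strong = log10(O_PVSt),
    strong, moderate, supporting at 1/2, 1/4, 1/8 of it; benign thresholds
    mirror with negative sign.
    """
    c = math.log10(o_pvst)
    return {
        "very_strong": c, "strong": c / 2, "moderate": c / 4,
        "supporting": c / 8,
    }


def assign_evidence(llr: float, prior: float = 0.1,
                    o_pvst: float = 350.0) -> str:
    """Map one LLRp value to an ACMG/AMP-style evidence category."""
    if not np.isfinite(llr):
        raise ValueError(f"non-finite LLRp: {llr}")
    t = evidence_thresholds(o_pvst)
    if llr >= t["very_strong"]:
        return "PS3_very_strong"
    if llr >= t["strong"]:
        return "PS3_strong"
    if llr >= t["moderate"]:
        return "PS3_moderate"
    if llr >= t["supporting"]:
        return "PS3_supporting"
    if llr <= -t["strong"]:
        return "BS3_strong"
    if llr <= -t["moderate"]:
        return "BS3_moderate"
    if llr <= -t["supporting"]:
        return "BS3_supporting"
    return "indeterminate"


def _fit_densities(pos_scores: np.ndarray, neg_scores: np.ndarray,
                   bandwidth: float | None = None
                   ) -> tuple[EpanechnikovKDE, EpanechnikovKDE, float, float]:
    d_pos = EpanechnikovKDE(bandwidth).fit(pos_scores)
    d_neg = EpanechnikovKDE(bandwidth).fit(neg_scores)
    rng_all = np.concatenate([pos_scores, neg_scores])
    span = float(np.ptp(rng_all)) or 1.0
    floor_pos = 1.0 / (10.0 * pos_scores.size * span)
    floor_neg = 1.0 / (10.0 * neg_scores.size * span)
    return d_pos, d_neg, floor_pos, floor_neg


def _llr_at(s: np.ndarray, d_pos, d_neg, floor_pos: float, floor_neg: float
            ) -> tuple[np.ndarray, np.ndarray]:
    dp = d_pos(s)
    dn = d_neg(s)
    floored = (dp < floor_pos) | (dn < floor_neg)
    return np.log10(np.maximum(dp, floor_pos) /
                    np.maximum(dn, floor_neg)), floored


def compute_llr(effect_map: pd.DataFrame, refs: pd.DataFrame,
                n_boot: int = 1000, seed: int = 0,
                prior: float = 0.1, o_pvst: float = 350.0,
                bandwidth: float | None = None) -> pd.DataFrame:
    """Per-variant log10 likelihood ratio of pathogenicity with bootstrap CI.

    Densities of the positive and negative reference score sets are
    estimated with Epanechnikov KDEs (Sheather-Jones bandwidths) and floored
    at 1/(10 n range) before the ratio, so LLRp stays finite outside one
    set's support (such points carry a ``floored`` flag). Confidence
    intervals come from a percentile bootstrap over reference-set
    resampling. The result covers every scored variant in the map.
    """
    if "score" in refs.columns:
        # reference set carries its own scores (e.g. from another map)
        labeled = refs.dropna(subset=["score"]).copy()
        labeled["label"] = labeled["label"].map(_normalize_label)
    else:
        labeled = assemble_labeled_scores(effect_map, refs)
    pos = labeled.loc[labeled["label"] == "positive", "score"].to_numpy()
    neg = labeled.loc[labeled["label"] == "negative", "score"].to_numpy()
    if pos.size < 5 or neg.size < 5:
        raise ValueError("need >= 5 scored reference variants per label")

    d_pos, d_neg, fp_, fn_ = _fit_densities(pos, neg, bandwidth)
    out = effect_map.dropna(subset=["score"]).copy().reset_index(drop=True)
    s = out["score"].to_numpy(dtype=float)
    llr, floored = _llr_at(s, d_pos, d_neg, fp_, fn_)
    out["llr"] = llr
    out["llr_floored"] = floored

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, s.size))
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        try:
            db_pos, db_neg, bfp, bfn = _fit_densities(bp, bn, bandwidth)
            boots[b], _ = _llr_at(s, db_pos, db_neg, bfp, bfn)
        except ValueError:  # degenerate resample: reuse point estimate
            boots[b] = llr
    out["llr_ci_lo"] = np.percentile(boots, 2.5, axis=0)
    out["llr_ci_hi"] = np.percentile(boots, 97.5, axis=0)
    out["evidence"] = [assign_evidence(v, prior, o_pvst) for v in out["llr"]]
    out.attrs["prior"] = prior
    out.attrs["o_pvst"] = o_pvst
    out.attrs["n_positive"] = int(pos.size)
    out.attrs["n_negative"] = int(neg.size)
    return out


@dataclass
class _Fitted:
    d_pos: EpanechnikovKDE
    d_neg: EpanechnikovKDE
    floor_pos: float
    floor_neg: float


class LlrCalibrator(BaseEstimator):
    """Sklearn-style calibrator from reference scores to LLRp and evidence.

    ``fit(X, y)`` takes reference scores ``X`` (1d array or a DataFrame with
    a ``score`` column) and labels ``y`` (clinical label strings or 0/1 with
    1 = pathogenic); ``predict(X)`` returns LLRp for new scores, and
    ``predict_evidence(X)`` the ACMG/AMP-style categories. Curve summaries
    for the training reference are exposed as ``curve_``, ``aubprc_`` and
    ``r80bp_``.
    """

    def __init__(self, prior: float = 0.1, o_pvst: float = 350.0,
                 bandwidth: float | None = None):
        self.prior = prior
        self.o_pvst = o_pvst
        self.bandwidth = bandwidth

    @staticmethod
    def _scores_1d(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X["score"].to_numpy(dtype=float)
        return np.asarray(X, dtype=float).ravel()

    def fit(self, X, y):
        s = self._scores_1d(X)
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            pos_mask = np.array([_normalize_label(v) == "positive" for v in y])
        else:
            pos_mask = y.astype(bool)
        pos, neg = s[pos_mask], s[~pos_mask]
        if pos.size < 5 or neg.size < 5:
            raise ValueError("need >= 5 reference scores per label")
        d_pos, d_neg, fp_, fn_ = _fit_densities(pos, neg, self.bandwidth)
        self._fitted_ = _Fitted(d_pos, d_neg, fp_, fn_)
        labeled = pd.DataFrame({
            "score": s,
            "label": np.where(pos_mask, "positive", "negative"),
        })
        self.curve_ = balanced_precision_recall(labeled)
        self.aubprc_ = aubprc(self.curve_)
        self.r80bp_ = r80bp(self.curve_)
        self.n_positive_ = int(pos.size)
        self.n_negative_ = int(neg.size)
        return self

    def predict(self, X) -> np.ndarray:
        f = self._fitted_
        llr, _ = _llr_at(self._scores_1d(X), f.d_pos, f.d_neg,
                         f.floor_pos, f.floor_neg)
        return llr

    def predict_evidence(self, X) -> np.ndarray:
        return np.array([assign_evidence(v, self.prior, self.o_pvst)
                         for v in self.predict(X)])
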