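"""Readers and writers for the pipeline's tabular formats.

Counts bundles travel as TSV (tile, condition, replicate, variant, count,
depth); variant-effect maps as MaveDB-style score CSV (hgvs_pro, score, se,
df, well_measured, extra columns preserved, '#' comment lines allowed);
reference sets as CSV (variant, label, source). Readers validate and
reject malformed input rather than coercing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .variants import parse_variant, format_variant

__all__ = [
    "read_counts", "write_counts",
    "read_scores", "write_scores",
    "read_reference", "write_reference",
    "write_one_letter_mapping",
    "RunConfig",
]

COUNT_COLUMNS = ["tile", "condition", "replicate", "variant", "count", "depth"]
VALID_CONDITIONS = {"pre", "post", "wt_control"}
SCORE_REQUIRED = ["hgvs_pro", "score", "se", "df"]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts bundle TSV, validating schema and condition tokens."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: no records")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_cond = df[~df["condition"].isin(VALID_CONDITIONS)]
    if len(bad_cond):
        line = int(bad_cond.index[0]) + 2  # 1-based, after header
        raise ValueError(
            f"{path}:{line}: unknown condition {bad_cond['condition'].iloc[0]!r}")
    for col in ("count", "depth"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}:{line}: non-integer {col!r} value")
    if (df["count"] < 0).any():
        line = int(df.index[(df["count"] < 0)][0]) + 2
        raise ValueError(f"{path}:{line}: negative count")
    return df[COUNT_COLUMNS + [c for c in df.columns if c not in COUNT_COLUMNS]]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a MaveDB-style score CSV into the internal map representation.

    ``hgvs_pro`` becomes the internal ``variant`` column; unrecognized
    columns are preserved; duplicate variants are an error.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no records")
    missing = [c for c in SCORE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dupes = df[df["hgvs_pro"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"{path}: duplicate hgvs_pro {dupes['hgvs_pro'].iloc[0]!r}")
    df = df.rename(columns={"hgvs_pro": "variant"})
    # re-canonicalize notation so joins across files are reliable
    df["variant"] = df["variant"].map(lambda v: format_variant(parse_variant(v)))
    return df


def write_scores(effect_map: pd.DataFrame, path: str | Path,
                 comments: list[str] | None = None) -> None:
    """Write a variant-effect map as MaveDB-style score CSV."""
    out = effect_map.rename(columns={"variant": "hgvs_pro"})
    first = [c for c in SCORE_REQUIRED if c in out.columns]
    out = out[first + [c for c in out.columns if c not in first]]
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read a reference-set CSV: variant, label in {P,LP,B,LB,PB}, source."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no records")
    for col in ("variant", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df["variant"] = df["variant"].map(lambda v: format_variant(parse_variant(v)))
    if "source" not in df.columns:
        df["source"] = "unspecified"
    return df


def write_reference(refs: pd.DataFrame, path: str | Path) -> None:
    refs.to_csv(path, index=False)


def write_one_letter_mapping(variants: pd.Series, path: str | Path) -> None:
    """Emit a three-letter to one-letter notation mapping table.

    Useful for MaveDB interoperability, where one-letter notation is common.
    """
    rows = []
    for v in variants:
        pv = parse_variant(v)
        alt = "*" if pv.alt_aa == "*" else pv.alt_aa
        rows.append((format_variant(pv), f"p.{pv.ref_aa}{pv.position}{alt}"))
    pd.DataFrame(rows, columns=["hgvs_pro", "one_letter"]).to_csv(
        path, sep="\t", index=False)


_CONFIG_VERSION = 1


@dataclass
class RunConfig:
    """Fully resolved stage parameters for a reproducible run.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    version: int = _CONFIG_VERSION
    simulate: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
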