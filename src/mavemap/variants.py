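"""Coding sequence, codon-level mutagenesis space, and protein variants.

Represents an ORF together with its TileSeq tiling, parses and formats
HGVS-like protein substitution notation (``p.Ala5Val``), and enumerates the
full protein-level substitution space with NNK- and SNV-accessibility flags
derived from the standard genetic code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AA_ORDER",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "STOP",
    "OrfSequence",
    "ProteinVariant",
    "VariantSpace",
    "VariantParseError",
    "ReferenceMismatchError",
    "parse_variant",
    "format_variant",
    "classify_variant",
    "enumerate_variant_space",
    "nnk_amino_acids",
    "snv_amino_acids",
]

STOP = "*"

#: canonical amino-acid ordering used for substitution profiles
AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP,
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_BASES = "ACGT"
#: NNK degenerate codon set: any base at positions 1-2, G or T at position 3
NNK_CODONS = [a + b + c for a in _BASES for b in _BASES for c in "GT"]


class VariantParseError(ValueError):
    """Raised when protein-variant notation cannot be parsed."""


class ReferenceMismatchError(ValueError):
    """Raised when a variant's reference residue disagrees with the ORF."""


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class ProteinVariant:
    """A single amino-acid substitution in ``p.RefPosAlt`` notation.

    ``position`` is the 1-based codon index; ``ref_aa``/``alt_aa`` are
    one-letter codes with ``*`` for a stop.
    """

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"non-positive position: {self.position}")
        for aa, role in ((self.ref_aa, "ref"), (self.alt_aa, "alt")):
            if aa not in ONE_TO_THREE:
                raise VariantParseError(f"unknown {role} residue code: {aa!r}")
        if self.ref_aa == STOP:
            raise VariantParseError("reference residue may not be a stop")

    @property
    def klass(self) -> str:
        """Variant class: nonsense iff alt is stop, synonymous iff alt == ref."""
        if self.alt_aa == STOP:
            return "nonsense"
        if self.alt_aa == self.ref_aa:
            return "synonymous"
        return "missense"

    def __str__(self) -> str:
        return format_variant(self)


_HGVS_RE = re.compile(
    r"^(?:p\.)?(?P<ref>[A-Za-z\*]{1,3})(?P<pos>-?\d+)(?P<alt>[A-Za-z\*]{1,3}|=)$"
)


def _decode_aa(token: str, role: str) -> str:
    if token in ("*", "Ter"):
        return STOP
    if len(token) == 3:
        if token not in THREE_TO_ONE:
            raise VariantParseError(f"unknown {role} residue code: {token!r}")
        return THREE_TO_ONE[token]
    if len(token) == 1:
        if token.upper() not in ONE_TO_THREE:
            raise VariantParseError(f"unknown {role} residue code: {token!r}")
        return token.upper()
    raise VariantParseError(f"unknown {role} residue code: {token!r}")


def parse_variant(text: str) -> ProteinVariant:
    """Parse HGVS-like protein substitution notation.

    Accepts three-letter (``p.Ala5Val``), one-letter (``p.A5V``), ``Ter`` or
    ``*`` stops, and ``=`` for a synonymous change (``p.Gly10=``).
    """
    m = _HGVS_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"unparseable variant notation: {text!r}")
    ref = _decode_aa(m.group("ref"), "ref")
    pos = int(m.group("pos"))
    if pos < 1:
        raise VariantParseError(f"non-positive position in {text!r}: {pos}")
    alt_token = m.group("alt")
    alt = ref if alt_token == "=" else _decode_aa(alt_token, "alt")
    return ProteinVariant(position=pos, ref_aa=ref, alt_aa=alt)


def format_variant(v: ProteinVariant) -> str:
    """Canonical three-letter notation, e.g. ``p.Ala5Val`` / ``p.Trp33Ter``."""
    return f"p.{ONE_TO_THREE[v.ref_aa]}{v.position}{ONE_TO_THREE[v.alt_aa]}"


@dataclass
class OrfSequence:
    """An open reading frame with its protein translation and tile layout.

    Tiles are half-open 1-based codon ranges ``(start, stop)`` covering every
    codon exactly once; the default layout mimics a TileSeq design of ~150 bp
    amplicons (five tiles for a SOD1-sized ORF).
    """

    nucleotides: str
    tile_boundaries: list[tuple[int, int]] = field(default_factory=list)
    protein: str = field(init=False)

    def __init__(self, nucleotides: str, n_tiles: int | None = None,
                 tile_boundaries: list[tuple[int, int]] | None = None):
        nt = nucleotides.upper().replace("U", "T")
        if len(nt) % 3 != 0:
            raise ValueError(f"ORF length {len(nt)} not divisible by 3")
        if not nt.startswith("ATG"):
            raise ValueError("ORF must start with ATG")
        if set(nt) - set(_BASES):
            raise ValueError("ORF contains non-ACGT characters")
        self.nucleotides = nt
        prot = str(Seq(nt).translate())
        # trailing stop codon is allowed but not part of the protein
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            raise ValueError("internal stop codon in ORF")
        self.protein = prot
        n_codons = len(prot)
        if tile_boundaries is not None:
            self.tile_boundaries = list(tile_boundaries)
        else:
            if n_tiles is None:
                n_tiles = max(1, round(n_codons / 31))  # ~5 tiles for 154 codons
            bounds = []
            base = n_codons // n_tiles
            extra = n_codons % n_tiles
            start = 1
            for i in range(n_tiles):
                size = base + (1 if i < extra else 0)
                bounds.append((start, start + size))
                start += size
            self.tile_boundaries = bounds
        self._check_tiles()

    def _check_tiles(self) -> None:
        covered = []
        for start, stop in self.tile_boundaries:
            covered.extend(range(start, stop))
        if sorted(covered) != list(range(1, len(self.protein) + 1)):
            raise ValueError("tiles must cover all codons exactly once")

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "OrfSequence":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single FASTA record, found {len(records)}")
        return cls(str(records[0].seq), **kwargs)

    def codon(self, position: int) -> str:
        """Reference codon at a 1-based position."""
        if not 1 <= position <= len(self.protein):
            raise IndexError(f"codon position {position} out of range")
        return self.nucleotides[3 * (position - 1): 3 * position]

    def tile_of(self, position: int) -> int:
        """1-based tile index containing a codon position."""
        for i, (start, stop) in enumerate(self.tile_boundaries, start=1):
            if start <= position < stop:
                return i
        raise IndexError(f"position {position} not covered by any tile")


def classify_variant(v: ProteinVariant, orf: OrfSequence) -> str:
    """Classify against the ORF, checking the reference residue."""
    if v.position > len(orf.protein):
        raise ReferenceMismatchError(
            f"position {v.position} beyond protein length {len(orf.protein)}")
    expected = orf.protein[v.position - 1]
    if v.ref_aa != expected:
        raise ReferenceMismatchError(
            f"reference mismatch at {v.position}: variant says {v.ref_aa}, "
            f"ORF has {expected}")
    return v.klass


def nnk_amino_acids() -> set[str]:
    """Amino acids (plus stop) encodable by the 32 NNK codons."""
    return {_translate_codon(c) for c in NNK_CODONS}


def snv_amino_acids(codon: str) -> set[str]:
    """Amino acids (plus stop) reachable by a single-base change of a codon."""
    out = set()
    for i in range(3):
        for b in _BASES:
            if b != codon[i]:
                out.add(_translate_codon(codon[:i] + b + codon[i + 1:]))
    return out


@dataclass
class VariantSpace:
    """All protein-level substitutions of an ORF with accessibility flags."""

    orf: OrfSequence
    table: pd.DataFrame  # variant, position, ref_aa, alt_aa, klass, flags

    def __len__(self) -> int:
        return len(self.table)

    def missense(self) -> pd.DataFrame:
        return self.table[self.table["klass"] == "missense"]

    def summary(self) -> dict:
        """Denominators for map-coverage reporting.

        Protein-level counts collapse codon multiplicity (one entry per
        position x alternate residue); the SNV-accessible subset counts
        substitutions reachable by a single nucleotide change.
        """
        mis = self.missense()
        return {
            "n_positions": int(self.table["position"].nunique()),
            "n_missense": int(len(mis)),
            "n_missense_snv": int(mis["snv_accessible"].sum()),
            "n_nonsense": int((self.table["klass"] == "nonsense").sum()),
            "n_synonymous": int((self.table["klass"] == "synonymous").sum()),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enumerate_variant_space(orf: OrfSequence) -> VariantSpace:
    """Enumerate every substitution, nonsense, and synonymous change.

    One row per (position, alt amino acid): 19 missense + 1 nonsense +
    1 synonymous per codon. ``nnk_accessible`` is true iff some NNK codon
    encodes the alt residue (a property of the code: true everywhere);
    ``snv_accessible`` iff a single-base mutant of the reference codon does.
    The initiator Met position and stops at the final codon are retained but
    flagged, since downstream analyses exclude them by default.
    """
    nnk = nnk_amino_acids()
    last = len(orf.protein)
    rows = []
    for pos in range(1, last + 1):
        ref = orf.protein[pos - 1]
        codon = orf.codon(pos)
        snv = snv_amino_acids(codon)
        alts = [a for a in AA_ORDER if a != ref] + [STOP, ref]
        for alt in alts:
            v = ProteinVariant(pos, ref, alt)
            rows.append({
                "variant": format_variant(v),
                "position": pos,
                "ref_aa": ref,
                "alt_aa": alt,
                "klass": v.klass,
                "nnk_accessible": alt in nnk,
                "snv_accessible": alt in snv,
                "start_codon": pos == 1,
                "terminal_stop": alt == STOP and pos == last,
                "tile": orf.tile_of(pos),
            })
    return VariantSpace(orf=orf, table=pd.DataFrame(rows))
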