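"""Fixed biological reference knowledge for p53 classification.

Houses the transcript exon↔codon map, protein domain intervals (DNA-binding
domain and its L2/L3 loops), the amino-acid polarity/charge grouping used by
the disruptive-mutation rule, and the evolutionary-action (EAp53) score
lookup table.

All coordinates are 1-based inclusive protein residue numbers, following
HGVS protein convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ParseError, ValidationError

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("tp53kit").joinpath("data", name)))


def _read_table(path, required_cols: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"reference file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty reference file: {path}") from None
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


@dataclass(frozen=True)
class TranscriptModel:
    """Protein-space exon map of a single transcript.

    ``exons`` is an ordered tuple of ``(exon_number, first_codon,
    last_codon)`` with 1-based inclusive codon intervals that jointly tile
    ``1..protein_length`` without gaps or overlaps.
    """

    gene_symbol: str
    transcript_label: str
    protein_length: int
    exons: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        if self.protein_length < 1:
            raise ValidationError("protein_length must be positive")
        prev_num = None
        cursor = 1
        for num, first, last in self.exons:
            if first > last:
                raise ValidationError(f"exon {num}: first_codon > last_codon")
            if prev_num is not None and num <= prev_num:
                raise ValidationError("exons not strictly ordered by exon_number")
            if first != cursor:
                raise ValidationError(
                    f"exon table has a gap or overlap at codon {min(first, cursor)}"
                )
            cursor = last + 1
            prev_num = num
        if cursor != self.protein_length + 1:
            raise ValidationError(
                f"exons cover 1..{cursor - 1}, expected 1..{self.protein_length}"
            )

    def codon_to_exon(self, position: int) -> int:
        """Return the exon number whose codon interval contains ``position``."""
        if not 1 <= position <= self.protein_length:
            raise ValidationError(
                f"codon {position} out of range 1..{self.protein_length}"
            )
        for num, first, last in self.exons:
            if first <= position <= last:
                return num
        raise AssertionError("unreachable: exon map tiles the protein")


@dataclass(frozen=True)
class DomainMap:
    """Named protein domain intervals; must include DBD with its L2/L3 loops."""

    domains: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        names = {name for name, _, _ in self.domains}
        for required in ("DBD", "L2", "L3"):
            if required not in names:
                raise ValidationError(f"domain map must define {required!r}")
        spans = {name: (a, b) for name, a, b in self.domains}
        for name, a, b in self.domains:
            if not 1 <= a <= b:
                raise ValidationError(f"domain {name}: bad interval {a}..{b}")
        dbd = spans["DBD"]
        for loop in ("L2", "L3"):
            a, b = spans[loop]
            if not (dbd[0] <= a and b <= dbd[1]):
                raise ValidationError(f"{loop} interval not contained in DBD")

    def domains_of(self, position: int) -> frozenset[str]:
        """All domain names whose interval contains ``position`` (may be empty)."""
        if position < 1:
            raise ValidationError("position must be >= 1")
        return frozenset(
            name for name, a, b in self.domains if a <= position <= b
        )

    def span(self, name: str) -> tuple[int, int]:
        for nm, a, b in self.domains:
            if nm == name:
                return (a, b)
        raise KeyError(name)


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Polarity/charge group per standard residue."""

    groups: Mapping[str, str]

    def __post_init__(self):
        covered = set(self.groups)
        if covered != STANDARD_RESIDUES:
            raise ValidationError(
                "property table must cover exactly the 20 standard residues; "
                f"missing={sorted(STANDARD_RESIDUES - covered)}, "
                f"extra={sorted(covered - STANDARD_RESIDUES)}"
            )

    def group_of(self, residue: str) -> str:
        if residue not in STANDARD_RESIDUES:
            raise ValidationError(f"nonstandard residue code: {residue!r}")
        return self.groups[residue]

    def same_group(self, a: str, b: str) -> bool:
        return self.group_of(a) == self.group_of(b)


@dataclass(frozen=True)
class EAScoreTable:
    """(ref, position, alt) → evolutionary-action score in [0, 100].

    Absence of a triple is a value (``None``), never an error and never a
    silent zero.
    """

    scores: Mapping[tuple[str, int, str], float]
    source: str = ""

    def __post_init__(self):
        ref_at: dict[int, str] = {}
        for (ref, pos, alt), score in self.scores.items():
            if not 0.0 <= score <= 100.0:
                raise ValidationError(
                    f"EA score out of [0,100] for {ref}{pos}{alt}: {score}"
                )
            seen = ref_at.setdefault(pos, ref)
            if seen != ref:
                raise ValidationError(
                    f"conflicting reference residues at position {pos}: {seen} vs {ref}"
                )

    def lookup(self, ref: str, position: int, alt: str) -> Optional[float]:
        return self.scores.get((ref, position, alt))


def load_transcript_model(
    path, gene_symbol: str = "TP53", transcript_label: str = "canonical"
) -> TranscriptModel:
    """Load a transcript exon table (columns: exon, first_codon, last_codon)."""
    df = _read_table(path, ["exon", "first_codon", "last_codon"])
    exons = []
    for i, row in df.iterrows():
        try:
            exons.append(
                (int(row["exon"]), int(row["first_codon"]), int(row["last_codon"]))
            )
        except (TypeError, ValueError):
            raise ParseError(f"{path}: malformed exon row at line {i + 2}") from None
    protein_length = max(last for _, _, last in exons)
    return TranscriptModel(
        gene_symbol=gene_symbol,
        transcript_label=transcript_label,
        protein_length=protein_length,
        exons=tuple(sorted(exons)),
    )


def load_domain_map(path) -> DomainMap:
    """Load a domain interval table (columns: name, start, end)."""
    df = _read_table(path, ["name", "start", "end"])
    domains = []
    for i, row in df.iterrows():
        try:
            domains.append((str(row["name"]), int(row["start"]), int(row["end"])))
        except (TypeError, ValueError):
            raise ParseError(f"{path}: malformed domain row at line {i + 2}") from None
    return DomainMap(domains=tuple(domains))


def load_property_table(path) -> ResiduePropertyTable:
    """Load the residue → polarity/charge group table (columns: residue, group)."""
    df = _read_table(path, ["residue", "group"])
    groups = {}
    for _, row in df.iterrows():
        res = str(row["residue"]).strip()
        if res in groups:
            raise ValidationError(f"duplicate residue {res!r} in property table")
        groups[res] = str(row["group"]).strip()
    return ResiduePropertyTable(groups=groups)


def load_ea_score_table(path) -> EAScoreTable:
    """Load an EA score table (columns: ref, pos, alt, score)."""
    df = _read_table(path, ["ref", "pos", "alt", "score"])
    scores = {}
    for i, row in df.iterrows():
        try:
            key = (str(row["ref"]).strip(), int(row["pos"]), str(row["alt"]).strip())
            scores[key] = float(row["score"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: malformed score row at line {i + 2}") from None
    return EAScoreTable(scores=scores, source=str(path))


def default_transcript_model() -> TranscriptModel:
    """Bundled canonical TP53 exon map (393 residues, coding exons 2–11)."""
    return load_transcript_model(
        _data_path("tp53_exons.tsv"), gene_symbol="TP53", transcript_label="TP53-canonical"
    )


def default_domain_map(
    l2: Optional[tuple[int, int]] = None, l3: Optional[tuple[int, int]] = None
) -> DomainMap:
    """Bundled p53 domain intervals, with optional L2/L3 loop overrides."""
    dm = load_domain_map(_data_path("tp53_domains.tsv"))
    if l2 is None and l3 is None:
        return dm
    overrides = {"L2": l2, "L3": l3}
    domains = tuple(
        (name, *(overrides[name] or (a, b))) if name in overrides else (name, a, b)
        for name, a, b in dm.domains
    )
    return DomainMap(domains=domains)


def default_property_table() -> ResiduePropertyTable:
    """Bundled polarity/charge grouping of the 20 standard residues."""
    return load_property_table(_data_path("aa_property_groups.tsv"))


def synthetic_ea_score_table() -> EAScoreTable:
    """Bundled SYNTHETIC hotspot EA scores (placeholders, not server values)."""
    return load_ea_score_table(_data_path("synthetic_ea_scores.tsv"))


def default_pathway_map_path() -> Path:
    return _data_path("pathway_map.tsv")


@dataclass(frozen=True)
class ReferenceBundle:
    """All reference objects the classifier needs, loaded together."""

    transcript: TranscriptModel
    domains: DomainMap
    properties: ResiduePropertyTable
    ea_scores: Optional[EAScoreTable] = None

    @classmethod
    def default(cls, ea_scores: Optional[EAScoreTable] = None) -> "ReferenceBundle":
        return cls(
            transcript=default_transcript_model(),
            domains=default_domain_map(),
            properties=default_property_table(),
            ea_scores=ea_scores,
        )
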