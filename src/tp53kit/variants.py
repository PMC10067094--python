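"""HGVS protein-change parsing and per-variant functional annotation.

The classification rule implemented here is the standard disruptive /
nondisruptive dichotomy for p53: inactivating mutations (nonsense,
frameshift, splice site) are disruptive, as are missense substitutions that
fall inside the L2 or L3 loop of the DNA-binding domain AND swap the residue
to a different polarity/charge group. Everything else is nondisruptive.

Missense variants with an evolutionary-action (EAp53) score are additionally
labelled high-risk (score > 75) or low-risk (score ≤ 75).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .exceptions import ParseError, ValidationError
from .reference import (
    DomainMap,
    EAScoreTable,
    ResiduePropertyTable,
    TranscriptModel,
)

# internal stop symbol; "X", "*" and "Ter" all normalize to this
STOP = "*"

EFFECTS = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "inframe_indel",
    "synonymous",
    "other",
)

TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "splice"})

_SUBST_RE = re.compile(r"^([A-Z])(\d+)(Ter|[A-Z*=])$")
_FS_RE = re.compile(r"^([A-Z*])(\d+)([A-Za-z]*)fs(?:\*?(?:\d+|\?))?(?:Ter(?:\d+|\?))?$")
_INDEL_RE = re.compile(
    r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?(del|dup|ins|delins)([A-Za-z*]*)$"
)


@dataclass(frozen=True)
class ProteinVariant:
    """A parsed protein-level variant with a normalized effect class."""

    gene: str
    raw_hgvs: str
    ref_residue: Optional[str]
    position: Optional[int]
    alt_residue: Optional[str]
    effect: str

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect class: {self.effect!r}")
        if self.effect in ("missense", "nonsense", "synonymous"):
            if self.ref_residue is None or self.position is None or self.alt_residue is None:
                raise ValidationError(
                    f"{self.effect} variant must carry ref, position and alt"
                )

    @property
    def is_truncating(self) -> bool:
        return self.effect in TRUNCATING_EFFECTS


def _strip_prefix(text: str) -> str:
    s = text.strip()
    if s.startswith("p."):
        s = s[2:]
    if s.startswith("(") and s.endswith(")"):
        s = s[1:-1]
    return s


def parse_hgvs_p(text: str, gene: str = "TP53") -> ProteinVariant:
    """Parse a protein-change string into a normalized :class:`ProteinVariant`.

    Accepted dialects: with or without a ``p.`` prefix; stop encoded as
    ``X``, ``*`` or ``Ter``; frameshifts as ``<ref><pos>…fs[*n]``; in-frame
    events via ``del``/``ins``/``dup``; splice variants flagged by a
    ``splice`` token (e.g. the MAF-style ``X331_splice``).

    Raises :class:`ParseError` on anything unrecognized — malformed input is
    never silently skipped.
    """
    if not text or not str(text).strip():
        raise ParseError("empty protein-change string")
    s = _strip_prefix(str(text))

    if "splice" in s.lower():
        return ProteinVariant(gene, text, None, None, None, "splice")

    m = _SUBST_RE.match(s)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt in ("X", "*", "Ter"):
            return ProteinVariant(gene, text, ref, pos, STOP, "nonsense")
        if alt == "=" or alt == ref:
            return ProteinVariant(gene, text, ref, pos, ref, "synonymous")
        return ProteinVariant(gene, text, ref, pos, alt, "missense")

    m = _FS_RE.match(s)
    if m:
        return ProteinVariant(gene, text, m.group(1), int(m.group(2)), None, "frameshift")

    m = _INDEL_RE.match(s)
    if m:
        return ProteinVariant(gene, text, m.group(1), int(m.group(2)), None, "inframe_indel")

    raise ParseError(f"unparseable protein change: {text!r}")


def format_hgvs_p(variant: ProteinVariant) -> str:
    """Render the normalized form (inverse of :func:`parse_hgvs_p` for
    substitutions; other effects echo their raw text)."""
    if variant.effect in ("missense", "nonsense", "synonymous"):
        return f"{variant.ref_residue}{variant.position}{variant.alt_residue}"
    return _strip_prefix(variant.raw_hgvs)


def eap53_class(score: Optional[float], effect: str) -> str:
    """EAp53 risk class: high_risk if score > 75, low_risk if ≤ 75.

    Applies to missense variants with a score only; everything else is
    ``not_applicable``.
    """
    if score is None or effect != "missense":
        return "not_applicable"
    if not 0.0 <= score <= 100.0:
        raise ValidationError(f"EA score out of [0,100]: {score}")
    return "high_risk" if score > 75.0 else "low_risk"


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Per-variant classification bundle."""

    variant: ProteinVariant
    is_truncating: bool
    exon: Optional[int]
    in_dbd: bool
    in_l2_or_l3: bool
    is_disruptive: bool
    ea_score: Optional[float]
    eap53_class: str

    def __post_init__(self):
        if self.is_truncating and not self.is_disruptive:
            raise ValidationError("truncating variants are disruptive by definition")
        if self.eap53_class != "not_applicable" and (
            self.variant.effect != "missense" or self.ea_score is None
        ):
            raise ValidationError("EAp53 class requires a scored missense variant")


def annotate_variant(
    variant: ProteinVariant,
    model: TranscriptModel,
    domains: DomainMap,
    properties: ResiduePropertyTable,
    ea_table: Optional[EAScoreTable] = None,
    ea_score: Optional[float] = None,
) -> FunctionalAnnotation:
    """Produce the full functional annotation for one parsed variant.

    ``ea_score`` (an explicit per-variant score, e.g. from a table column)
    takes precedence over a lookup in ``ea_table``.
    """
    pos = variant.position
    if pos is not None and pos > model.protein_length:
        raise ValidationError(
            f"{variant.raw_hgvs}: position {pos} exceeds protein length "
            f"{model.protein_length}"
        )

    exon = model.codon_to_exon(pos) if pos is not None else None
    doms = domains.domains_of(pos) if pos is not None else frozenset()
    in_dbd = "DBD" in doms
    in_loop = bool({"L2", "L3"} & doms)

    is_trunc = variant.is_truncating
    disruptive = is_trunc
    if variant.effect == "missense" and in_loop:
        if not properties.same_group(variant.ref_residue, variant.alt_residue):
            disruptive = True

    score = None
    if variant.effect == "missense":
        if ea_score is not None:
            score = float(ea_score)
            if not 0.0 <= score <= 100.0:
                raise ValidationError(f"EA score out of [0,100]: {score}")
        elif ea_table is not None:
            score = ea_table.lookup(variant.ref_residue, pos, variant.alt_residue)

    return FunctionalAnnotation(
        variant=variant,
        is_truncating=is_trunc,
        exon=exon,
        in_dbd=in_dbd,
        in_l2_or_l3=in_loop,
        is_disruptive=disruptive,
        ea_score=score,
        eap53_class=eap53_class(score, variant.effect),
    )
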