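"""Clinical/variant table I/O, cohort filters, and patient-level TP53 status.

Tables are tab-delimited with a header. The clinical table carries one row
per patient (covariates + overall-survival outcome); the variant table is a
MAF-like subset with one row per mutation (patient id, gene symbol, protein
change, optional variant classification and EA score columns).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .reference import ReferenceBundle
from .variants import parse_hgvs_p, annotate_variant

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "smoking",
    "histology",
    "stage",
    "multi_organ_met",
    "egfr_status",
    "os_months",
    "os_event",
    "ici_treated",
]

VARIANT_COLUMNS = ["patient_id", "gene", "protein_change"]

_CATEGORICALS = {
    "sex": {"male", "female", "unknown"},
    "smoking": {"smoker", "nonsmoker", "unknown"},
    "histology": {"LUAD", "LUSC", "ASC", "other", "unknown"},
    "stage": {"I", "II", "III", "IV", "unknown"},
    "multi_organ_met": {"yes", "no", "unknown", "not_applicable"},
    "egfr_status": {"mutant", "wild_type", "unknown"},
}

#: classifications counted as splice-site events when the protein change
#: string itself carries no splice token
SPLICE_CLASSIFICATIONS = {"Splice_Site", "Splice_Region"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding (the convention of printed cohort tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _to_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n", "", "nan"):
        return False
    raise ValidationError(f"cannot interpret boolean value {v!r}")


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate the clinical table.

    Unknown category levels are mapped to ``"unknown"`` with a warning, not
    dropped. Structural violations (duplicate ids, an OS event without an OS
    time, a multi-organ-metastasis flag outside stage IV) raise
    :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty clinical table: {path}") from None
    if "patient_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'patient_id'")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical column(s) {missing}")

    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id(s): {dups[:5]}")

    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    out["age_years"] = pd.to_numeric(df["age_years"], errors="raise").astype(int)

    for col, allowed in _CATEGORICALS.items():
        vals = df[col].fillna("unknown").astype(str).str.strip()
        bad = ~vals.isin(allowed)
        if bad.any():
            warnings.warn(
                f"{col}: {int(bad.sum())} unknown category value(s) mapped to 'unknown'",
                stacklevel=2,
            )
            vals = vals.where(~bad, "unknown")
        out[col] = vals

    out["os_months"] = pd.to_numeric(df["os_months"], errors="coerce")
    out["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    has_t, has_e = out["os_months"].notna(), out["os_event"].notna()
    if (has_t != has_e).any():
        bad_ids = out.loc[has_t != has_e, "patient_id"].tolist()
        raise ValidationError(
            f"os_months and os_event must be present together; offending ids: {bad_ids[:5]}"
        )
    if (out.loc[has_t, "os_months"] < 0).any():
        raise ValidationError("negative os_months")
    if not out.loc[has_e, "os_event"].isin([0, 1]).all():
        raise ValidationError("os_event must be 0 (censored) or 1 (death)")

    not_iv = out["stage"] != "IV"
    bad_met = not_iv & (out["multi_organ_met"] != "not_applicable")
    if bad_met.any():
        bad_ids = out.loc[bad_met, "patient_id"].tolist()
        raise ValidationError(
            f"multi_organ_met set outside stage IV for: {bad_ids[:5]}"
        )

    out["ici_treated"] = df["ici_treated"].map(_to_bool)
    return out


def read_variant_table(path) -> pd.DataFrame:
    """Read the MAF-subset variant table; rows are preserved verbatim.

    No classification happens here. Optional columns
    ``variant_classification`` and ``ea_score`` are carried through when
    present.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty variant table: {path}") from None
    if list(df.columns) == VARIANT_COLUMNS[:1] and df.empty:
        pass
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing variant column(s) {missing}")
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str),
            "gene": df["gene"].astype(str),
            "protein_change": df["protein_change"].where(df["protein_change"].notna(), None),
        }
    )
    out["variant_classification"] = (
        df["variant_classification"].where(df["variant_classification"].notna(), None)
        if "variant_classification" in df.columns
        else None
    )
    out["ea_score"] = (
        pd.to_numeric(df["ea_score"], errors="coerce")
        if "ea_score" in df.columns
        else np.nan
    )
    return out


@dataclass
class Cohort:
    """A clinical table, its variant table, and (optionally) the per-variant
    TP53 annotations computed from them."""

    clinical: pd.DataFrame
    variants: pd.DataFrame
    annotations: Optional[pd.DataFrame] = None
    skipped: list = field(default_factory=list)

    def __post_init__(self):
        known = set(self.clinical["patient_id"])
        orphan = set(self.variants["patient_id"]) - known
        if orphan:
            raise ValidationError(
                f"variant rows reference unknown patient ids: {sorted(orphan)[:5]}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.clinical)


def annotate_cohort(cohort: Cohort, refs: ReferenceBundle) -> Cohort:
    """Parse and annotate every TP53 variant row; non-TP53 rows are left to
    the landscape module.

    Unparseable TP53 rows become explicit skip records (logged), never silent
    drops.
    """
    rows, skipped = [], []
    tp53 = cohort.variants[cohort.variants["gene"] == "TP53"]
    for idx, row in tp53.iterrows():
        pc = row["protein_change"]
        vc = row["variant_classification"]
        text = pc
        if (text is None or str(text).strip() == "") and vc in SPLICE_CLASSIFICATIONS:
            text = "splice"
        try:
            pv = parse_hgvs_p(str(text))
        except ParseError as exc:
            skipped.append({"row": int(idx), "patient_id": row["patient_id"],
                            "protein_change": pc, "reason": str(exc)})
            logger.warning("skipping unparseable TP53 row %s: %s", idx, exc)
            continue
        if pv.effect != "splice" and vc in SPLICE_CLASSIFICATIONS:
            pv = parse_hgvs_p("splice")
        score = row["ea_score"]
        ann = annotate_variant(
            pv,
            refs.transcript,
            refs.domains,
            refs.properties,
            ea_table=refs.ea_scores,
            ea_score=None if pd.isna(score) else float(score),
        )
        rows.append(
            {
                "row": int(idx),
                "patient_id": row["patient_id"],
                "protein_change": pv.raw_hgvs,
                "effect": pv.effect,
                "position": pv.position,
                "is_truncating": ann.is_truncating,
                "exon": ann.exon,
                "in_dbd": ann.in_dbd,
                "in_l2_or_l3": ann.in_l2_or_l3,
                "is_disruptive": ann.is_disruptive,
                "ea_score": ann.ea_score,
                "eap53_class": ann.eap53_class,
            }
        )
    ann_df = pd.DataFrame(
        rows,
        columns=[
            "row", "patient_id", "protein_change", "effect", "position",
            "is_truncating", "exon", "in_dbd", "in_l2_or_l3", "is_disruptive",
            "ea_score", "eap53_class",
        ],
    )
    return Cohort(cohort.clinical, cohort.variants, ann_df, skipped)


def apply_cohort_filters(
    cohort: Cohort,
    require_stage_advanced: bool = False,
    require_ici_naive: bool = False,
    require_os: bool = False,
) -> tuple[Cohort, dict]:
    """Apply the survival-analysis cohort filters in order stage → ICI → OS.

    Returns the filtered cohort and a report of counts removed per criterion.
    """
    clin = cohort.clinical
    report = {"input": len(clin)}
    if require_stage_advanced:
        keep = clin["stage"].isin(["III", "IV"])
        report["removed_stage"] = int((~keep).sum())
        clin = clin[keep]
    if require_ici_naive:
        keep = ~clin["ici_treated"]
        report["removed_ici"] = int((~keep).sum())
        clin = clin[keep]
    if require_os:
        keep = clin["os_months"].notna()
        report["removed_no_os"] = int((~keep).sum())
        clin = clin[keep]
    report["output"] = len(clin)
    if len(clin) == 0:
        warnings.warn("cohort filters removed every patient", stacklevel=2)
    ids = set(clin["patient_id"])
    variants = cohort.variants[cohort.variants["patient_id"].isin(ids)]
    ann = (
        cohort.annotations[cohort.annotations["patient_id"].isin(ids)]
        if cohort.annotations is not None
        else None
    )
    return Cohort(clin.reset_index(drop=True), variants.reset_index(drop=True), ann,
                  cohort.skipped), report


DEFAULT_PRECEDENCE = ("high_risk", "low_risk", "truncating", "other")

FOUR_GROUP_LABELS = {
    "high_risk": "EAp53 high-risk",
    "low_risk": "EAp53 low-risk",
    "truncating": "truncating",
    "other": "other",
    "wild_type": "WT",
}


def aggregate_patient_tp53(
    cohort: Cohort, precedence: tuple = DEFAULT_PRECEDENCE
) -> pd.DataFrame:
    """Collapse per-variant annotations to one TP53 status record per patient.

    Boolean fields are ORs over the patient's variants; patients carrying
    several TP53 variants get their four-group label from the configured
    precedence (default: EAp53 high-risk > low-risk > truncating > other).
    Row order of the variant table never affects the result.
    """
    if cohort.annotations is None:
        raise ValidationError("annotate_cohort must run before aggregation")
    ann = cohort.annotations
    records = []
    by_patient = dict(tuple(ann.groupby("patient_id"))) if len(ann) else {}
    for pid in cohort.clinical["patient_id"]:
        g = by_patient.get(pid)
        if g is None or g.empty:
            records.append(
                dict(patient_id=pid, has_mutation=False, has_missense=False,
                     has_truncating=False, has_exon8=False,
                     has_nondisruptive_missense=False, best_eap53="none",
                     wild_type=True, four_group="WT",
                     precedence_applied=False)
            )
            continue
        has_missense = bool((g["effect"] == "missense").any())
        has_trunc = bool(g["is_truncating"].any())
        has_exon8 = bool((g["exon"] == 8).any())
        has_nd_missense = bool(
            ((g["effect"] == "missense") & ~g["is_disruptive"]).any()
        )
        classes = set(g["eap53_class"])
        best = "high" if "high_risk" in classes else ("low" if "low_risk" in classes else "none")
        eligible = set()
        if "high_risk" in classes:
            eligible.add("high_risk")
        if "low_risk" in classes:
            eligible.add("low_risk")
        if has_trunc:
            eligible.add("truncating")
        if not eligible:
            eligible.add("other")
        label_key = next(k for k in precedence if k in eligible)
        records.append(
            dict(
                patient_id=pid,
                has_mutation=True,
                has_missense=has_missense,
                has_truncating=has_trunc,
                has_exon8=has_exon8,
                has_nondisruptive_missense=has_nd_missense,
                best_eap53=best,
                wild_type=False,
                four_group=FOUR_GROUP_LABELS[label_key],
                precedence_applied=len(eligible) > 1,
            )
        )
    return pd.DataFrame(records).set_index("patient_id")


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Printed-table style cohort summary: counts and percentages per
    category, age median/range, and the patient-level TP53 mutation
    frequency.

    Percentages use non-missing denominators and half-up rounding to one
    decimal place.
    """
    clin = cohort.clinical
    rows = []

    def add(variable, category, count, denom):
        pct = round_half_up(100.0 * count / denom) if denom else float("nan")
        rows.append(dict(variable=variable, category=category,
                         count=count, denominator=denom, percent=pct))

    n = len(clin)
    age = clin["age_years"]
    rows.append(dict(variable="age_years", category="median", count=float(age.median()),
                     denominator=n, percent=float("nan")))
    rows.append(dict(variable="age_years", category="min", count=int(age.min()),
                     denominator=n, percent=float("nan")))
    rows.append(dict(variable="age_years", category="max", count=int(age.max()),
                     denominator=n, percent=float("nan")))

    for var in ("sex", "smoking", "histology", "stage"):
        counts = clin[var].value_counts()
        for cat, cnt in counts.items():
            add(var, cat, int(cnt), n)

    stage_iv = clin[clin["stage"] == "IV"]
    for cat, cnt in stage_iv["multi_organ_met"].value_counts().items():
        add("multi_organ_met_stage_iv", cat, int(cnt), len(stage_iv))

    if cohort.annotations is not None:
        mut_patients = cohort.annotations["patient_id"].nunique()
        add("tp53_status", "mutant", int(mut_patients), n)
        add("tp53_status", "wild_type", n - int(mut_patients), n)

    return pd.DataFrame(rows)
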