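"""Comparison schemes over patient-level TP53 status, plus the
clinical-association and mutation-pattern contingency tests.

Test selection follows the usual rule, made explicit and recorded with every
table: Fisher's exact test whenever any expected cell count is below 5,
otherwise the chi-square test with continuity correction (for 2×2 tables).
All tests are two-sided.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, aggregate_patient_tp53
from .exceptions import ValidationError

SCHEMES = (
    "missense_vs_others",
    "nondisruptive_vs_others",
    "exon8_vs_others",
    "eap53_vs_others",
    "four_group",
)


def stratify(status: pd.DataFrame, scheme: str) -> pd.Series:
    """Assign every patient a group label under a named scheme.

    ``status`` is the output of :func:`tp53kit.cohort.aggregate_patient_tp53`
    (indexed by patient id). Dichotomous schemes label the exposed class by
    name and pool everyone else — including wild type — into ``others``.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "missense_vs_others":
        labels = np.where(status["has_missense"], "missense", "others")
    elif scheme == "nondisruptive_vs_others":
        labels = np.where(status["has_nondisruptive_missense"], "nondisruptive", "others")
    elif scheme == "exon8_vs_others":
        labels = np.where(status["has_exon8"], "exon8", "others")
    elif scheme == "eap53_vs_others":
        labels = np.where(status["best_eap53"] == "high", "eap53_high", "others")
    else:
        labels = status["four_group"].to_numpy()
    out = pd.Series(labels, index=status.index, name=scheme)
    if out.nunique() < 2:
        warnings.warn(f"scheme {scheme}: only one group present", stacklevel=2)
    return out


def choose_test(table: np.ndarray) -> str:
    """Deterministic test selection for a contingency table.

    Returns ``"fisher"`` if any expected count < 5, ``"chi2"`` otherwise,
    and ``"not_testable"`` when a row or column margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.min() < 0:
        raise ValidationError("negative count in contingency table")
    if t.sum() == 0 or (t.sum(axis=1) == 0).any():
        return "not_testable"  # an empty group: no comparison exists
    if (t.sum(axis=0) == 0).any():
        return "fisher"  # no variation in the outcome: exact test, p = 1
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return "fisher" if (expected < 5).any() else "chi2"


def test_2x2(table) -> tuple[str, Optional[float]]:
    """Two-sided 2×2 test with the Fisher/chi-square selection rule.

    Returns ``(test_name, p_value)``; degenerate tables come back as
    ``("not_testable", None)`` rather than raising.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    which = choose_test(t)
    if which == "not_testable":
        return which, None
    if which == "fisher":
        _, p = stats.fisher_exact(t, alternative="two-sided")
    else:
        res = stats.chi2_contingency(t, correction=True)
        p = float(res[1])
    return which, float(min(p, 1.0))


def _assoc_row(variable: str, exposed: pd.Series, outcome: pd.Series) -> dict:
    """2×2 association between a binary exposure and TP53 status."""
    mask = exposed.notna() & outcome.notna()
    e, o = exposed[mask].astype(bool), outcome[mask].astype(bool)
    table = np.array(
        [
            [int((e & o).sum()), int((e & ~o).sum())],
            [int((~e & o).sum()), int((~e & ~o).sum())],
        ]
    )
    test, p = test_2x2(table)
    return dict(
        variable=variable,
        test=test,
        p_value=p,
        table=table.tolist(),
        n=int(mask.sum()),
    )


def clinical_association_tests(cohort: Cohort, status: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """TP53-mutant vs wild-type association with sex, smoking, age
    dichotomized at 65, and single- vs multiple-organ metastasis (stage IV
    patients only)."""
    if status is None:
        status = aggregate_patient_tp53(cohort)
    clin = cohort.clinical.set_index("patient_id")
    mutated = status["has_mutation"].reindex(clin.index)

    rows = [
        _assoc_row("sex_male", (clin["sex"] == "male").where(clin["sex"] != "unknown"), mutated),
        _assoc_row(
            "smoker",
            (clin["smoking"] == "smoker").where(clin["smoking"] != "unknown"),
            mutated,
        ),
        _assoc_row("age_gt65", clin["age_years"] > 65, mutated),
    ]
    iv = clin[clin["stage"] == "IV"]
    met = (iv["multi_organ_met"] == "yes").where(iv["multi_organ_met"].isin(["yes", "no"]))
    rows.append(_assoc_row("multi_organ_met", met, mutated.reindex(iv.index)))
    return pd.DataFrame(rows)


def mutation_pattern_tests(annotations: pd.DataFrame) -> dict:
    """Per-exon and DBD vs non-DBD contrasts of truncating vs missense
    variant location, plus the hotspot frequency table.

    Contrasts are per-variant (all alterations as the denominator). Variants
    without a protein position (splice) enter exon/domain contrasts only
    through the "elsewhere" margin being undefined, so they are excluded
    from location tables; the exclusion count is reported.
    """
    ann = annotations
    classed = ann[ann["effect"].isin(["missense"]) | ann["is_truncating"]]
    located = classed[classed["position"].notna()]
    n_unlocated = len(classed) - len(located)

    is_trunc = located["is_truncating"].to_numpy()
    exon_rows = []
    for exon in sorted(located["exon"].dropna().unique()):
        in_exon = (located["exon"] == exon).to_numpy()
        table = np.array(
            [
                [int((is_trunc & in_exon).sum()), int((is_trunc & ~in_exon).sum())],
                [int((~is_trunc & in_exon).sum()), int((~is_trunc & ~in_exon).sum())],
            ]
        )
        test, p = test_2x2(table)
        exon_rows.append(dict(exon=int(exon), test=test, p_value=p, table=table.tolist()))
    exon_tests = pd.DataFrame(exon_rows)

    in_dbd = located["in_dbd"].to_numpy()
    dbd_table = np.array(
        [
            [int((is_trunc & in_dbd).sum()), int((is_trunc & ~in_dbd).sum())],
            [int((~is_trunc & in_dbd).sum()), int((~is_trunc & ~in_dbd).sum())],
        ]
    )
    dbd_test, dbd_p = test_2x2(dbd_table)

    total = len(ann)
    hotspot = (
        ann["protein_change"]
        .value_counts()
        .rename_axis("protein_change")
        .reset_index(name="count")
    )
    hotspot["frequency"] = hotspot["count"] / total if total else np.nan

    return dict(
        exon_tests=exon_tests,
        domain_test=dict(test=dbd_test, p_value=dbd_p, table=dbd_table.tolist()),
        hotspot_table=hotspot,
        n_variants=total,
        n_excluded_no_position=int(n_unlocated),
        truncating_fraction=float(classed["is_truncating"].mean()) if len(classed) else np.nan,
    )
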