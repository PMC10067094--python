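"""Genomic-landscape comparison between EAp53 high-risk patients (HR group)
and all other patients (OT group): per-gene mutation frequencies, pathway
alteration rates, and tumor mutation burden.

All frequencies are patient-level — a patient with two mutations in the same
gene counts once — matching the oncoprint convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, aggregate_patient_tp53
from .exceptions import ValidationError
from .stratify import test_2x2

#: variant classifications excluded from TMB and frequency eligibility
SYNONYMOUS_CLASSIFICATIONS = {"Silent", "Synonymous", "synonymous"}


def hr_ot_partition(cohort: Cohort, status: Optional[pd.DataFrame] = None) -> pd.Series:
    """Boolean Series (indexed by patient id): True = HR group (carries an
    EAp53 high-risk mutation), False = OT group (everyone else)."""
    if status is None:
        status = aggregate_patient_tp53(cohort)
    return status["best_eap53"] == "high"


def _mutated_patients(variants: pd.DataFrame) -> pd.DataFrame:
    """Patient×gene presence table (nonsynonymous rows only)."""
    v = variants
    if "variant_classification" in v.columns:
        v = v[~v["variant_classification"].isin(SYNONYMOUS_CLASSIFICATIONS)]
    return v[["patient_id", "gene"]].drop_duplicates()


def gene_frequency_compare(
    cohort: Cohort,
    partition: pd.Series,
    min_patients: int = 3,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene HR vs OT mutation-frequency comparison.

    One row per gene with patient-level mutated/total counts per group, the
    chosen test and two-sided p-value, sorted by HR-group frequency. Genes
    mutated in fewer than ``min_patients`` patients overall are reported but
    flagged untested.
    """
    if not set(cohort.clinical["patient_id"]) <= set(partition.index):
        raise ValidationError("partition must cover the whole cohort")
    hr_ids = set(partition.index[partition])
    ot_ids = set(partition.index[~partition]) & set(cohort.clinical["patient_id"])
    hr_total, ot_total = len(hr_ids & set(cohort.clinical["patient_id"])), len(ot_ids)

    presence = _mutated_patients(cohort.variants)
    rows = []
    for gene, grp in presence.groupby("gene"):
        carriers = set(grp["patient_id"])
        hr_mut, ot_mut = len(carriers & hr_ids), len(carriers & ot_ids)
        table = [[hr_mut, hr_total - hr_mut], [ot_mut, ot_total - ot_mut]]
        tested = (hr_mut + ot_mut) >= min_patients
        test, p = test_2x2(table) if tested else ("untested", None)
        rows.append(
            dict(
                gene=gene,
                hr_mutated=hr_mut, hr_total=hr_total,
                ot_mutated=ot_mut, ot_total=ot_total,
                hr_frequency=hr_mut / hr_total if hr_total else np.nan,
                ot_frequency=ot_mut / ot_total if ot_total else np.nan,
                test=test, p_value=p,
            )
        )
    out = pd.DataFrame(rows).sort_values(
        ["hr_frequency", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    if bh_adjust and len(out):
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        out["p_adjusted"] = adj
    return out


def load_pathway_map(path) -> dict[str, set]:
    """Read a two-column (pathway, gene) TSV into a pathway → gene-set map."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"pathway", "gene"} <= set(df.columns):
        raise ValidationError(f"{path}: pathway map needs columns pathway, gene")
    mapping: dict[str, set] = {}
    for _, row in df.iterrows():
        mapping.setdefault(row["pathway"], set()).add(row["gene"])
    if any(len(g) == 0 for g in mapping.values()):
        raise ValidationError("pathway with empty gene set")
    return mapping


def pathway_aggregate(
    cohort: Cohort, partition: pd.Series, pathway_map: dict[str, set]
) -> pd.DataFrame:
    """Per-pathway alteration frequency per group with a 2×2 test.

    A patient is pathway-altered if at least one mapped gene carries at least
    one (nonsynonymous) mutation. Pathways with no member gene observed in
    the cohort are reported as empty and untested.
    """
    hr_ids = set(partition.index[partition]) & set(cohort.clinical["patient_id"])
    ot_ids = set(partition.index[~partition]) & set(cohort.clinical["patient_id"])
    presence = _mutated_patients(cohort.variants)
    genes_seen = set(presence["gene"])
    rows = []
    for pathway, genes in sorted(pathway_map.items()):
        if not (genes & genes_seen):
            rows.append(dict(pathway=pathway, test="empty", p_value=None,
                             hr_altered=0, hr_total=len(hr_ids),
                             ot_altered=0, ot_total=len(ot_ids),
                             hr_frequency=0.0, ot_frequency=0.0))
            continue
        altered = set(presence.loc[presence["gene"].isin(genes), "patient_id"])
        hr_alt, ot_alt = len(altered & hr_ids), len(altered & ot_ids)
        table = [[hr_alt, len(hr_ids) - hr_alt], [ot_alt, len(ot_ids) - ot_alt]]
        test, p = test_2x2(table)
        rows.append(
            dict(
                pathway=pathway, test=test, p_value=p,
                hr_altered=hr_alt, hr_total=len(hr_ids),
                ot_altered=ot_alt, ot_total=len(ot_ids),
                hr_frequency=hr_alt / len(hr_ids) if hr_ids else np.nan,
                ot_frequency=ot_alt / len(ot_ids) if ot_ids else np.nan,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TMBRecord:
    patient_id: str
    eligible_mutations: int
    panel_size_mb: float
    tmb: float


def compute_tmb(
    cohort: Cohort,
    panel_size_mb: float,
    eligible_classifications: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-patient tumor mutation burden: eligible mutations / panel Mb.

    Default eligibility: every variant whose classification is not
    synonymous/silent (nonsynonymous SNVs and indels). Patients with no
    variant rows get TMB 0.
    """
    if panel_size_mb <= 0:
        raise ValidationError("panel size must be positive (megabases)")
    v = cohort.variants
    if eligible_classifications is not None:
        v = v[v["variant_classification"].isin(set(eligible_classifications))]
    elif "variant_classification" in v.columns:
        v = v[~v["variant_classification"].isin(SYNONYMOUS_CLASSIFICATIONS)]
    counts = v.groupby("patient_id").size()
    out = pd.DataFrame({"patient_id": cohort.clinical["patient_id"]})
    out["eligible_mutations"] = (
        out["patient_id"].map(counts).fillna(0).astype(int)
    )
    out["panel_size_mb"] = float(panel_size_mb)
    out["tmb"] = out["eligible_mutations"] / panel_size_mb
    return out


def tmb_compare(tmb: pd.DataFrame, partition: pd.Series) -> dict:
    """Mann–Whitney U comparison of TMB between HR and OT groups.

    Exact enumeration when both groups have ≤ 20 patients and the data are
    tie-free; the tie-corrected normal approximation otherwise.
    """
    merged = tmb.set_index("patient_id").join(partition.rename("hr"))
    hr_vals = merged.loc[merged["hr"].astype(bool), "tmb"].to_numpy()
    ot_vals = merged.loc[~merged["hr"].astype(bool), "tmb"].to_numpy()
    if len(hr_vals) == 0 or len(ot_vals) == 0:
        raise ValidationError("both groups must be non-empty for TMB comparison")
    pooled = np.concatenate([hr_vals, ot_vals])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(hr_vals), len(ot_vals)) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(hr_vals, ot_vals, alternative="two-sided", method=method)
    return dict(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        hr_median=float(np.median(hr_vals)),
        ot_median=float(np.median(ot_vals)),
        hr_n=int(len(hr_vals)),
        ot_n=int(len(ot_vals)),
    )
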