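"""Landscape comparison: gene frequencies, pathway aggregation and TMB,
with an exact Mann-Whitney enumeration oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tp53kit import (
    Cohort,
    ReferenceBundle,
    ValidationError,
    aggregate_patient_tp53,
    compute_tmb,
    gene_frequency_compare,
    hr_ot_partition,
    pathway_aggregate,
    tmb_compare,
)


def mwu_exact_two_sided_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumeration of all assignments of
    the pooled ranks to the first group (tie-free data only)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(y)
    stats = []
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        stats.append(u)
    stats = np.array(stats)
    # two-sided: distance of U from its mean
    d_obs = abs(u_obs - n1n2 / 2)
    return float(np.mean(np.abs(stats - n1n2 / 2) >= d_obs - 1e-12))


def build_cohort(gene_presence: dict[str, list[str]], hr_ids: list[str],
                 all_ids: list[str], extra_variant_rows=None) -> tuple[Cohort, pd.Series]:
    """Construct a minimal annotated cohort where ``gene_presence`` maps each
    gene to the patients mutated in it; HR membership is forced through a
    high-scoring TP53 missense variant."""
    clinical = pd.DataFrame(
        [dict(patient_id=p, age_years=60, sex="male", smoking="smoker",
              histology="LUAD", stage="IV", multi_organ_met="no",
              egfr_status="wild_type", os_months=np.nan, os_event=np.nan,
              ici_treated=False) for p in all_ids]
    )
    rows = [dict(patient_id=p, gene="TP53", protein_change="R282W",
                 variant_classification="Missense_Mutation", ea_score=90.0)
            for p in hr_ids]
    for gene, patients in gene_presence.items():
        rows += [dict(patient_id=p, gene=gene, protein_change=None,
                      variant_classification="Missense_Mutation", ea_score=np.nan)
                 for p in patients]
    if extra_variant_rows:
        rows += extra_variant_rows
    variants = pd.DataFrame(rows, columns=["patient_id", "gene", "protein_change",
                                           "variant_classification", "ea_score"])
    from tp53kit import annotate_cohort

    cohort = annotate_cohort(Cohort(clinical, variants), ReferenceBundle.default())
    return cohort, hr_ot_partition(cohort)


class TestGeneFrequencies:
    def test_partition_conservation(self, annotated_cohort):
        part = hr_ot_partition(annotated_cohort)
        out = gene_frequency_compare(annotated_cohort, part)
        n = annotated_cohort.n_patients
        assert ((out["hr_total"] + out["ot_total"]) == n).all()
        assert out["hr_frequency"].between(0, 1).all()
        assert (out["hr_mutated"] <= out["hr_total"]).all()

    def test_gene_in_every_patient_gives_p_1(self):
        ids = [f"P{i}" for i in range(40)]
        cohort, part = build_cohort({"UBIQ": ids}, hr_ids=ids[:20], all_ids=ids)
        out = gene_frequency_compare(cohort, part).set_index("gene")
        assert out.loc["UBIQ", "p_value"] == pytest.approx(1.0)

    def test_rare_genes_flagged_untested(self):
        ids = [f"P{i}" for i in range(40)]
        cohort, part = build_cohort({"RARE": ids[:1]}, hr_ids=ids[:20], all_ids=ids)
        out = gene_frequency_compare(cohort, part, min_patients=3).set_index("gene")
        assert out.loc["RARE", "test"] == "untested"

    def test_constructed_enrichment_detected_with_power(self):
        """Gene mutated in 30% of HR vs 5% of OT (n=100 per group) is flagged
        significant in at least 90% of seeds."""
        hits = 0
        seeds = 40
        for seed in range(seeds):
            rng = np.random.default_rng(1000 + seed)
            hr_ids = [f"H{i}" for i in range(100)]
            ot_ids = [f"O{i}" for i in range(100)]
            carriers = [p for p in hr_ids if rng.uniform() < 0.30]
            carriers += [p for p in ot_ids if rng.uniform() < 0.05]
            cohort, part = build_cohort({"GENE1": carriers}, hr_ids=hr_ids,
                                        all_ids=hr_ids + ot_ids)
            out = gene_frequency_compare(cohort, part).set_index("gene")
            p = out.loc["GENE1", "p_value"]
            hits += (p is not None) and (p < 0.05)
        assert hits / seeds >= 0.90

    def test_bh_adjustment_column(self, annotated_cohort):
        part = hr_ot_partition(annotated_cohort)
        out = gene_frequency_compare(annotated_cohort, part, bh_adjust=True)
        tested = out[out["p_value"].notna()]
        assert (tested["p_adjusted"] >= tested["p_value"] - 1e-12).all()


class TestPathways:
    PMAP = {"DDR": {"ATM", "BRCA2"}, "RTK": {"EGFR"}}

    def test_or_semantics_single_member_gene(self):
        ids = [f"P{i}" for i in range(10)]
        cohort, part = build_cohort({"BRCA2": [ids[0]]}, hr_ids=ids[:5], all_ids=ids)
        out = pathway_aggregate(cohort, part, self.PMAP).set_index("pathway")
        assert out.loc["DDR", "hr_altered"] == 1  # altered via BRCA2 alone

    def test_symmetric_groups_give_p_1(self):
        ids = [f"P{i}" for i in range(40)]
        carriers = ids[:5] + ids[20:25]  # 5 in each half
        cohort, part = build_cohort({"ATM": carriers}, hr_ids=ids[:20], all_ids=ids)
        out = pathway_aggregate(cohort, part, self.PMAP).set_index("pathway")
        assert out.loc["DDR", "p_value"] == pytest.approx(1.0)

    def test_absent_pathway_reported_empty(self):
        ids = [f"P{i}" for i in range(6)]
        cohort, part = build_cohort({}, hr_ids=ids[:3], all_ids=ids)
        out = pathway_aggregate(cohort, part, self.PMAP).set_index("pathway")
        assert out.loc["RTK", "test"] == "empty"

    def test_constructed_ddr_enrichment(self):
        rng = np.random.default_rng(77)
        hr_ids = [f"H{i}" for i in range(100)]
        ot_ids = [f"O{i}" for i in range(100)]
        carriers = [p for p in hr_ids if rng.uniform() < 0.35]
        carriers += [p for p in ot_ids if rng.uniform() < 0.08]
        cohort, part = build_cohort({"ATM": carriers}, hr_ids=hr_ids,
                                    all_ids=hr_ids + ot_ids)
        out = pathway_aggregate(cohort, part, self.PMAP).set_index("pathway")
        assert out.loc["DDR", "hr_frequency"] > out.loc["DDR", "ot_frequency"]
        assert out.loc["DDR", "p_value"] < 0.05

    def test_pathway_frequency_dominates_member_genes(self, annotated_cohort):
        from tp53kit import load_pathway_map
        from tp53kit.reference import default_pathway_map_path

        part = hr_ot_partition(annotated_cohort)
        pmap = load_pathway_map(default_pathway_map_path())
        paths = pathway_aggregate(annotated_cohort, part, pmap).set_index("pathway")
        genes = gene_frequency_compare(annotated_cohort, part, min_patients=0).set_index("gene")
        for pathway, members in pmap.items():
            for gene in members & set(genes.index):
                for col in ("hr_frequency", "ot_frequency"):
                    assert paths.loc[pathway, col] >= genes.loc[gene, col] - 1e-12


class TestTMB:
    def test_simple_arithmetic(self):
        ids = ["P0"]
        rows = [dict(patient_id="P0", gene=f"G{i}", protein_change=None,
                     variant_classification="Missense_Mutation", ea_score=np.nan)
                for i in range(10)]
        cohort, _ = build_cohort({}, hr_ids=[], all_ids=ids, extra_variant_rows=rows)
        tmb = compute_tmb(cohort, 1.0).set_index("patient_id")
        assert tmb.loc["P0", "tmb"] == pytest.approx(10.0)

    def test_zero_mutations_zero_tmb(self):
        cohort, _ = build_cohort({}, hr_ids=[], all_ids=["P0"])
        tmb = compute_tmb(cohort, 1.0).set_index("patient_id")
        assert tmb.loc["P0", "tmb"] == 0.0

    def test_synonymous_excluded_by_default(self):
        rows = [dict(patient_id="P0", gene=f"G{i}", protein_change=None,
                     variant_classification="Missense_Mutation", ea_score=np.nan)
                for i in range(9)]
        rows += [dict(patient_id="P0", gene=f"S{i}", protein_change=None,
                      variant_classification="Silent", ea_score=np.nan)
                 for i in range(3)]
        cohort, _ = build_cohort({}, hr_ids=[], all_ids=["P0"], extra_variant_rows=rows)
        tmb = compute_tmb(cohort, 1.2).set_index("patient_id")
        assert tmb.loc["P0", "eligible_mutations"] == 9
        assert tmb.loc["P0", "tmb"] == pytest.approx(7.5)

    def test_nonpositive_panel_rejected(self):
        cohort, _ = build_cohort({}, hr_ids=[], all_ids=["P0"])
        with pytest.raises(ValidationError):
            compute_tmb(cohort, 0.0)


class TestTMBCompare:
    @staticmethod
    def _records(values_by_pid):
        return pd.DataFrame(
            [dict(patient_id=p, eligible_mutations=0, panel_size_mb=1.0, tmb=v)
             for p, v in values_by_pid.items()]
        )

    def test_separated_groups_exact_p(self):
        tmb = self._records({"A1": 1, "A2": 2, "A3": 3, "B1": 4, "B2": 5, "B3": 6})
        part = pd.Series([True] * 3 + [False] * 3,
                         index=["A1", "A2", "A3", "B1", "B2", "B3"])
        res = tmb_compare(tmb, part)
        assert res["method"] == "exact"
        assert res["u_statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(0.1)  # 2/C(6,3)=2/20

    def test_identical_groups_p_1(self):
        vals = {f"A{i}": float(i) for i in range(4)}
        vals.update({f"B{i}": float(i) for i in range(4)})
        part = pd.Series([k.startswith("A") for k in vals], index=list(vals))
        res = tmb_compare(self._records(vals), part)
        assert res["p_value"] == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            x = rng.uniform(0, 10, size=6)
            y = rng.uniform(0, 10, size=5)
            vals = {f"A{i}": v for i, v in enumerate(x)}
            vals.update({f"B{i}": v for i, v in enumerate(y)})
            part = pd.Series([k.startswith("A") for k in vals], index=list(vals))
            res = tmb_compare(self._records(vals), part)
            assert res["method"] == "exact"
            assert res["p_value"] == pytest.approx(mwu_exact_two_sided_oracle(x, y))

    def test_exact_and_asymptotic_agree_moderate_n(self):
        rng = np.random.default_rng(29)
        from scipy import stats as ss

        for _ in range(10):
            x = rng.normal(5, 1, size=15)
            y = rng.normal(5, 1, size=15)
            p_exact = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_asym = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p_exact == pytest.approx(p_asym, abs=0.01)

    def test_empty_group_rejected(self):
        tmb = self._records({"A1": 1.0, "A2": 2.0})
        part = pd.Series([True, True], index=["A1", "A2"])
        with pytest.raises(ValidationError):
            tmb_compare(tmb, part)

    def test_simulated_cohort_hr_group_has_higher_tmb(self, annotated_cohort):
        part = hr_ot_partition(annotated_cohort)
        tmb = compute_tmb(annotated_cohort, 1.2)
        res = tmb_compare(tmb, part)
        assert res["hr_median"] > res["ot_median"]
        assert res["p_value"] < 0.05
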