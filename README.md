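# tp53kit

Functional classification of TP53 mutations and prognostic stratification of
non-small cell lung cancer (NSCLC) cohorts.

TP53 is the most frequently mutated gene in NSCLC (~50% of patients), but its
variants are not functionally equivalent, and different classification
systems disagree about which carriers have the worst outlook. `tp53kit`
implements, as one tested pipeline, the classification systems that NSCLC
prognosis studies compare:

- **Effect classes** parsed from HGVS protein notation (missense, nonsense,
  frameshift, splice, in-frame indel, synonymous), with *truncating* =
  nonsense ∪ frameshift ∪ splice.
- **Exon location** of each variant on the canonical 393-residue protein
  (exon-8 mutations are one prognostic stratum of interest).
- **Disruptive vs nondisruptive**: a variant is disruptive if it is
  truncating, or if it is a missense substitution inside the L2 (163–195) or
  L3 (236–251) loop of the DNA-binding domain (DBD, residues 102–292) that
  swaps the residue to a different polarity/charge group; everything else is
  nondisruptive.
- **EAp53 risk**: missense variants with an evolutionary-action score are
  high-risk when the score exceeds 75, low-risk at or below 75. Scores are a
  lookup-table input (column in the variant table or a separate table); they
  are never computed here.

Patient-level strata are compared with the standard battery: Kaplan–Meier
curves and the log-rank test, Cox proportional-hazards models (univariate
and multivariate, adjusting for age > 65, sex, smoking and EGFR status),
Fisher/χ² contingency tests for clinical associations and mutation-location
patterns, and a genomic-landscape comparison of EAp53 high-risk (HR) vs all
other (OT) patients: per-gene frequencies, RTK / cell-cycle / DNA-damage-
repair pathway alteration rates, and tumor mutation burden (TMB, eligible
mutations per megabase, Mann–Whitney U).

A seeded synthetic cohort generator (`tp53kit.simulate`) emits the exact
clinical/variant TSV dialects the readers consume, plus a truth table, so the
whole pipeline runs and is tested with no external downloads.

## Worked example

Generate a 210-patient synthetic cohort and run the full analysis:

```sh
tp53kit simulate --seed 7 --out-dir sim
tp53kit run-all --clinical sim/clinical.tsv --variants sim/variants.tsv \
        --panel-mb 1.2 --out-dir out
```

`out/summary.tsv` holds the cohort table — e.g. at seed 7 the generator
reproduces the configured covariate mix (126/210 male = 60.0%, median age
65). `out/survival.json` records the filter cascade (210 → 89 patients after
keeping stage III/IV, ICI-naive patients with overall-survival data) and the
per-scheme results. For the EAp53 scheme at seed 7:

```
log-rank (eap53_high n=21 vs others n=68): p = 0.032
multivariate Cox, EAp53 high-risk indicator: HR 2.74 (95% CI 1.40–5.36), p = 0.003
```

i.e. EAp53 high-risk carriers die at roughly 2.7× the adjusted hazard of all
other patients — as expected, since the generator's only true TP53
prognostic effect is attached to the EAp53 high-risk state (default log-HR
ln 3.6; the estimate is attenuated at n=89). `out/landscape.json` shows the
matching landscape contrast: median TMB 7.1 mut/Mb in the HR group vs 4.2 in
the OT group (Mann–Whitney p < 1e-6).

The same stages are available as library calls (`parse_hgvs_p`,
`annotate_variant`, `aggregate_patient_tp53`, `stratify`,
`run_survival_analysis`, `gene_frequency_compare`, `tmb_compare`, ...); see
`docs/methods.md` for the model and every default.

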