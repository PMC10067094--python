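# Methods

This note documents the models and rules `tp53kit` implements, the defaults
it ships, and the choices made where the underlying conventions are genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate system and reference data

All coordinates are 1-based inclusive protein residue numbers (HGVS protein
convention) on the canonical 393-residue p53 protein. The bundled exon map
(`data/tp53_exons.tsv`) covers coding exons 2–11 and was derived from the
canonical transcript's CDS intron junctions (after coding positions 74, 96,
375, 559, 672, 782, 919, 993 and 1100 of the 1182-nt CDS); a codon split
across a junction is assigned to the exon containing its first base. This
yields exon 8 = codons 262–307, so the recurrent substitutions at codons 273,
282 and 298 are exon-8 variants. The exon table is validated on load: the
intervals must tile 1..393 with no gap or overlap, and `codon_to_exon` is
exhaustively scan-tested over every codon.

Domain intervals (`data/tp53_domains.tsv`): DNA-binding domain (DBD)
102–292 with the L2 loop at 163–195 and the L3 loop at 236–251 — the
boundaries conventional in the disruptive-classification literature — plus
transactivation, proline-rich, tetramerization and regulatory regions for
reporting. L2/L3 must lie inside the DBD (validated). The loop boundaries
are configurable (CLI `--loops`) because published loop definitions vary by
a few residues.

Residue polarity/charge groups (`data/aa_property_groups.tsv`): nonpolar
{G,A,V,L,I,P,F,M,W}, polar-uncharged {S,T,C,Y,N,Q}, positive {K,R,H},
negative {D,E}. This is the standard biochemistry grouping; it is shipped as
data rather than code so the one unstated choice in the disruptive rule is
auditable and overridable. Under it, Y236C stays within the polar-uncharged
group (nondisruptive) while R249S crosses groups (disruptive).

Evolutionary-action (EAp53) scores are consumed, never computed: either an
`ea_score` column in the variant table (which takes precedence) or a lookup
table keyed by (ref, position, alt). Scores must lie in [0, 100]; a missing
triple is a distinguished absent value, never a silent zero. The bundled
`data/synthetic_ea_scores.tsv` is a synthetic placeholder set for the
recurrent hotspots so examples run end to end; real analyses must supply
scores from the external EAp53 resource.

## Variant classification

`parse_hgvs_p` accepts the dialects that appear in MAF-style tables: with or
without a `p.` prefix, stop as `X`, `*` or `Ter` (normalized to one internal
symbol), frameshifts as `<ref><pos>…fs[*n]`, in-frame `del`/`ins`/`dup`
events, and splice variants flagged by a `splice` token or by the variant
classification column. Unparseable strings raise, and the cohort annotator
turns them into explicit skip records — malformed rows are never silently
dropped.

The classification rule:

- truncating ⇔ effect ∈ {nonsense, frameshift, splice};
- disruptive ⇔ truncating, or missense with position in L2 ∪ L3 and
  ref/alt in different polarity-charge groups; all else nondisruptive;
- EAp53 class (missense with a score only): high-risk ⇔ score > 75,
  low-risk ⇔ score ≤ 75.

Hence truncating ⊆ disruptive by construction (property-tested), and the
implementation is checked against an independent brute-force re-evaluation
over all 393 × 20 substitutions.

Decisions where the conventions are open:

- **In-frame indels** are non-truncating, nondisruptive, EAp53
  not-applicable, and excluded from the missense-vs-truncating dichotomies;
  they surface as an `other`/`inframe_indel` bucket so counts stay auditable.
- **Splice variants** carry no protein position: no exon, never in L2/L3,
  always truncating/disruptive.
- **Missense without an EA score** is EAp53 not-applicable and falls into
  the `other` bucket of the four-group split, with the count reported.

## Patient-level aggregation and schemes

Per patient: `has_missense`, `has_truncating`, `has_exon8` and
`has_nondisruptive_missense` are ORs over the patient's TP53 variants;
`best_eap53` is high if any variant is high-risk, else low if any is
low-risk. Patients with several TP53 variants get their four-group label by
a configurable precedence, default **EAp53 high-risk > low-risk >
truncating > other** — the high-risk state is the risk-defining exposure, so
it dominates. Every aggregation is invariant to variant row order (tested by
shuffling).

Schemes: `missense_vs_others`, `nondisruptive_vs_others` (any nondisruptive
*missense*; truncating variants are all disruptive, so after excluding
synonymous/in-frame events the nondisruptive mutation class is exactly the
nondisruptive missense set), `exon8_vs_others`, `eap53_vs_others`, and the
`four_group` split {EAp53 high-risk, EAp53 low-risk, truncating, WT} (+
`other`). In every dichotomous scheme the complement — including wild type —
is pooled as `others`, mirroring the combine-then-compare design in which
the non-exposed mutant class is first shown to be indistinguishable from
wild type and then merged with it.

## Statistics

- **Contingency tests** (clinical associations, mutation-location patterns,
  gene/pathway frequencies): Fisher's exact test whenever any expected cell
  count is below 5, otherwise χ² with continuity correction; all two-sided,
  α = 0.05, no multiplicity correction by default (an optional
  Benjamini–Hochberg column is available for the per-gene screen). A table
  with an empty group is reported not-testable; a table with no outcome
  variation is routed to Fisher (p = 1). The chosen test is recorded with
  every table. Exon/domain location contrasts are per-variant (all
  alterations as the denominator); splice variants, having no position, are
  excluded from location tables and the exclusion count is reported.
- **Kaplan–Meier / log-rank** via lifelines: product-limit curves
  (censoring at an event time processed after the events), k-group log-rank
  with χ² reference on k−1 df. Tested against the closed-form product
  limit, the empirical survival function (no censoring), and an independent
  hypergeometric observed-minus-expected oracle.
- **Cox proportional hazards** via the statsmodels partial-likelihood
  implementation. Ties method: Efron by default (better with
  monthly-resolution ties), Breslow by flag. Hazard ratios with Wald 95%
  CIs on the log-HR scale. Constant covariates and designs with fewer
  events than covariates are rejected; non-convergence is flagged on the
  result, not raised. Verified against a grid-search maximizer of the exact
  partial likelihood and by parameter-recovery simulation.
- **TMB**: eligible mutations (default: everything not classified
  synonymous/silent) divided by panel megabases; computed only when a panel
  size is supplied, since a small driver panel cannot support a TMB
  estimate. Group comparison by Mann–Whitney U — exact enumeration when
  both groups have ≤ 20 tie-free observations, tie-corrected normal
  approximation otherwise — verified against brute-force enumeration.

The survival analysis applies the cohort filters in the order stage III/IV →
ICI-naive → OS available, reporting counts removed at each step, and then
runs per scheme: KM per group, sub-comparisons against pure wild type, the
combined contrast, univariate Cox on the scheme indicator, and one
multivariate Cox adjusting for age > 65, sex, smoking and EGFR status.
Survival times are used as given in `os_months` (the time origin is the
upstream cohort's convention; not configurable). Patients with unknown
covariate levels are dropped from the affected model fit, with the fitted n
reported.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- n = 210 patients, TP53 prevalence 0.514; 15.7% of mutant patients carry a
  second TP53 variant (so alterations ≈ 1.16 × carriers).
- Mutation spectrum: eight recurrent hotspots (R282W, R158L, Y236C, E298X,
  R110L, R273C, R280K, Y220C) each weighted above 2% of alterations, plus
  class templates — missense concentrated in exons 5/7/8 of the DBD,
  nonsense/frameshift concentrated in exons 4 and 10 outside the DBD, and a
  splice fraction — calibrated so ≈31% of alterations are truncating.
- EA scores: fixed synthetic values for the hotspots; otherwise a
  two-component normal mixture (modes ≈50 and ≈85, weight 0.45 on the high
  mode, clipped to [0,100]) so both risk classes are populated at any
  realistic n.
- Covariates: 60% male, 50% smokers, ages ~N(65, 10) clipped to 34–87,
  histology 77/22/1% LUAD/LUSC/ASC, stages 4.3/3.8/14.8/75.2% (+1.9%
  unknown), multi-organ metastasis in 32.3% of stage IV. Covariates are
  independent of TP53 status by default (association parameters are not
  modelled). No patient is ICI-treated by default; OS is available for 41%
  of advanced-stage patients, giving ≈78 analyzable patients at n = 210.
- Survival: Weibull baseline (shape 1.2, scale 40 months — median ≈30
  months at zero linear predictor, a realistic advanced-NSCLC figure), with
  proportional hazards by construction. Default log-HRs: EAp53 high-risk
  ln 3.6, EGFR-mutant ln 0.30, male ln 2.0, all other exposures 0 — i.e.
  the EAp53 state is the only true TP53 prognostic effect, so the missense/
  exon-8/nondisruptive schemes show only the indirect effect of their
  overlap with high-risk carriers. Censoring: min(administrative horizon 60
  months, Exp(rate 0.008/month)).
- Landscape: per-gene Bernoulli background mutations with group-specific
  probabilities (e.g. EGFR 0.33/0.25, PTPRD 0.12/0.03 in HR/OT), EGFR
  clinical status tied to the simulated EGFR gene state, plus Poisson
  passenger mutations (mean 6 HR vs 3 OT over a long-tail gene list, 10%
  silent) so the TMB contrast is realized at panel size 1.2 Mb.

One root seed feeds six named substreams (covariates, TP53, EA, background,
survival, censoring), so extending one component never perturbs the draws of
another; outputs are byte-identical across reruns of the same seed. The TP53
reference residues come from a deterministic synthetic pseudo-sequence with
the hotspot residues patched in — the classifier never checks reference
residues against a sequence, so a reproducible placeholder suffices.

**What passing tests on synthetic data do and do not show.** The generator
realizes clean proportional hazards, independent censoring, exact category
frequencies and a known truth table; it does not emulate panel-specific
calling noise, allele fractions, covariate–mutation correlations (beyond
EGFR), cohort heterogeneity, or informative censoring. Green tests therefore
demonstrate that the pipeline's arithmetic, rules and estimators are correct
and well-calibrated under the stated model — not that any particular
clinical effect size generalizes to real cohorts.

## Numerical and engineering choices

- Percentages in cohort summaries: non-missing denominators, one decimal,
  half-up rounding (Decimal-based, matching printed clinical tables).
- Wald CIs use z = Φ⁻¹(0.975); log-rank p-values from the χ² upper tail.
- Degenerate inputs fail loudly: empty reference files, exon-map gaps,
  duplicate patient ids, OS event/time mismatches, a multi-organ-metastasis
  flag outside stage IV, non-positive survival times, out-of-range EA
  scores.
- All output files carry a provenance header (or JSON block) with the
  package version, input checksums and the echoed configuration; no
  timestamps, so reruns are byte-identical.
- Problem sizes in the test suite and acceptance script (e.g. 50 recovery
  seeds at n = 500; 1000 null replicates at n = 100; one 100k-patient
  prevalence check) were chosen as the smallest sizes at which the
  corresponding law-of-large-numbers or coverage statements are sharp.

## Known limitations

- DNA-level (c./g.) notation is not parsed; the unit of analysis is the
  protein change plus the MAF classification column.
- EAp53 scores must be supplied; variants absent from the score table fall
  into the `other` stratum rather than being imputed.
- The Cox layer has no time-varying covariates or competing risks.
- The four-group precedence for patients carrying both high-risk and
  truncating variants is a convention (high-risk dominates); reports flag
  every patient whose label it decided.
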