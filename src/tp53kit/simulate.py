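"""Synthetic NSCLC cohort generator.

Emits the exact clinical/variant table dialects the cohort reader consumes,
plus a truth table recording each patient's generative state, so the whole
pipeline is testable without external data and parameter-recovery
experiments are reproducible.

Defaults emulate the study conditions the analysis assumes: ~210 patients
with ~51.4% TP53 mutation prevalence, a hotspot-weighted mutation spectrum
concentrated in exons 5/7/8, ~31% truncating alterations enriched outside
the DNA-binding domain, evolutionary-action scores from a two-component
mixture spanning the 75-point risk threshold, covariates (60% male, 50%
smokers, stage mix dominated by stage IV), and Weibull survival with
group-specific hazard ratios plus administrative and random right-censoring.

Randomness comes from a single root seed split into named substreams
(covariates / TP53 / EA scores / background genes / survival / censoring),
so adding draws to one component never perturbs another.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .reference import (
    default_domain_map,
    default_property_table,
    default_transcript_model,
    synthetic_ea_score_table,
)

_STREAMS = ("covariates", "tp53", "ea", "background", "survival", "censoring")

#: hotspot protein changes with weights (each above 2% of TP53 alterations)
DEFAULT_HOTSPOTS = (
    ("R282W", 0.066),
    ("R158L", 0.050),
    ("Y236C", 0.040),
    ("E298X", 0.040),
    ("R110L", 0.030),
    ("R273C", 0.030),
    ("R280K", 0.025),
    ("Y220C", 0.025),
)

#: class templates filling the rest of the spectrum; truncating templates sum
#: (with E298X) to ≈0.31 of all alterations
DEFAULT_TEMPLATES = (
    ("missense_dbd", 0.374),
    ("missense_other", 0.050),
    ("nonsense_flank", 0.130),
    ("frameshift_flank", 0.100),
    ("splice", 0.040),
)

#: background gene → (P(mutated | HR group), P(mutated | OT group));
#: frequencies echo the oncoprint-style landscape contrast
DEFAULT_BACKGROUND_GENES = {
    "EGFR": (0.33, 0.25), "KRAS": (0.22, 0.29), "PTPRD": (0.12, 0.03),
    "STK11": (0.12, 0.16), "KEAP1": (0.11, 0.16), "MLL2": (0.10, 0.05),
    "CDKN2A": (0.10, 0.04), "PTPRT": (0.10, 0.03), "RB1": (0.09, 0.03),
    "STAG2": (0.05, 0.01), "B2M": (0.05, 0.01), "RBM10": (0.05, 0.09),
    "ATM": (0.08, 0.04), "BRCA2": (0.05, 0.02), "CHEK2": (0.04, 0.02),
    "ALK": (0.04, 0.05), "MET": (0.05, 0.04), "ERBB2": (0.04, 0.03),
    "BRAF": (0.04, 0.04), "ROS1": (0.02, 0.02), "RET": (0.02, 0.02),
    "CCND1": (0.04, 0.02), "CDK4": (0.03, 0.01), "CCNE1": (0.03, 0.01),
    "MLH1": (0.03, 0.01), "MSH2": (0.03, 0.01),
}

DEFAULT_PASSENGER_GENES = (
    "TTN", "MUC16", "RYR2", "LRP1B", "ZFHX4", "USH2A", "CSMD3", "FLG",
    "SPTA1", "XIRP2", "NAV3", "COL11A1", "ANK2", "PCDH15", "APOB",
)

DEFAULT_LOG_HAZARD_RATIOS = {
    "eap53_high": math.log(3.6),
    "missense": 0.0,
    "exon8": 0.0,
    "nondisruptive": 0.0,
    "male": math.log(2.0),
    "smoker": 0.0,
    "age_gt65": 0.0,
    "egfr_mutant": math.log(0.30),
}


@dataclass
class SimulationConfig:
    """Full generative specification for a synthetic cohort."""

    seed: int
    n_patients: int = 210
    tp53_prevalence: float = 0.514
    multi_mutation_fraction: float = 0.157  # P(second TP53 variant | mutant)
    spectrum: tuple = DEFAULT_HOTSPOTS + DEFAULT_TEMPLATES

    # EA score mixture for simulated missense variants (spans the 75 cutoff)
    ea_high_weight: float = 0.45
    ea_low_mean: float = 50.0
    ea_low_sd: float = 12.0
    ea_high_mean: float = 85.0
    ea_high_sd: float = 5.0

    # covariates
    male_prob: float = 0.60
    smoker_prob: float = 0.50
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_range: tuple = (34, 87)
    histology_probs: tuple = (("LUAD", 0.771), ("LUSC", 0.219), ("ASC", 0.010))
    stage_probs: tuple = (("I", 0.043), ("II", 0.038), ("III", 0.148),
                          ("IV", 0.752), ("unknown", 0.019))
    multi_organ_met_prob: float = 0.323  # among stage IV
    ici_treated_prob: float = 0.0
    os_available_prob: float = 0.41  # among advanced-stage ICI-naive patients

    # survival model
    weibull_shape: float = 1.2
    weibull_scale_months: float = 40.0
    log_hazard_ratios: dict = field(
        default_factory=lambda: dict(DEFAULT_LOG_HAZARD_RATIOS)
    )
    censor_horizon_months: float = 60.0
    censor_exp_rate: float = 0.008  # per month

    # landscape
    background_genes: dict = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_GENES)
    )
    passenger_genes: tuple = DEFAULT_PASSENGER_GENES
    passenger_lambda_hr: float = 6.0
    passenger_lambda_ot: float = 3.0
    passenger_silent_fraction: float = 0.10
    panel_size_mb: float = 1.2

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is mandatory and must be an integer")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        probs = [
            self.tp53_prevalence, self.multi_mutation_fraction, self.ea_high_weight,
            self.male_prob, self.smoker_prob, self.multi_organ_met_prob,
            self.ici_treated_prob, self.os_available_prob,
            self.passenger_silent_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0,1]")
        if any(w <= 0 for _, w in self.spectrum):
            raise ValidationError("spectrum weights must be positive")
        if self.weibull_shape <= 0 or self.weibull_scale_months <= 0:
            raise ValidationError("Weibull shape and scale must be positive")
        if self.censor_horizon_months <= 0:
            raise ValidationError("censoring horizon must be positive")
        if self.censor_exp_rate < 0:
            raise ValidationError("censoring rate must be non-negative")
        if self.panel_size_mb <= 0:
            raise ValidationError("panel size must be positive")
        for gene, (p_hr, p_ot) in self.background_genes.items():
            if not (0 <= p_hr <= 1 and 0 <= p_ot <= 1):
                raise ValidationError(f"background gene {gene}: bad probabilities")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spectrum" in raw:
            raw["spectrum"] = tuple((str(t), float(w)) for t, w in raw["spectrum"])
        for key in ("histology_probs", "stage_probs"):
            if key in raw:
                raw[key] = tuple((str(k), float(v)) for k, v in raw[key])
        if "background_genes" in raw:
            raw["background_genes"] = {
                g: tuple(v) for g, v in raw["background_genes"].items()
            }
        if "passenger_genes" in raw:
            raw["passenger_genes"] = tuple(raw["passenger_genes"])
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def pseudo_protein_sequence(length: int = 393) -> str:
    """Deterministic synthetic 393-residue sequence with the recurrent NSCLC
    hotspot residues patched in. NOT the real p53 sequence — the classifier
    never checks reference residues against a sequence, so a reproducible
    placeholder suffices for data generation."""
    rng = np.random.default_rng(20240101)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = list(rng.choice(aas, size=length))
    patches = {110: "R", 158: "R", 175: "R", 220: "Y", 236: "Y", 245: "G",
               248: "R", 249: "R", 273: "R", 280: "R", 282: "R", 298: "E"}
    for pos, res in patches.items():
        seq[pos - 1] = res
    return "".join(seq)


def simulate_survival(
    linear_predictor,
    shape: float,
    scale: float,
    horizon: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observed time, event) pairs under a Weibull baseline.

    Event times follow a proportional-hazards Weibull: the cumulative hazard
    is ``(t/scale)^shape * exp(lp)``. Observed time is the minimum of the
    event time, the administrative horizon, and an independent exponential
    censoring time; event = 1 iff death is observed first.
    """
    if shape <= 0 or scale <= 0:
        raise ValidationError("Weibull shape and scale must be positive")
    if horizon <= 0:
        raise ValidationError("censoring horizon must be positive")
    lp = np.asarray(linear_predictor, dtype=float)
    n = len(lp)
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


# position pools for the class templates (protein coordinates)
_DBD_HOT_RANGES = ((126, 187), (225, 261), (262, 292))   # exons 5/7/8 ∩ DBD
_NON_DBD_RANGES = ((33, 101), (293, 367))                # outside the DBD
_FLANK_RANGES = ((33, 125), (332, 367))                  # exons 4 and 10


def _pool(ranges) -> np.ndarray:
    return np.concatenate([np.arange(a, b + 1) for a, b in ranges])


@dataclass
class SimulatedCohort:
    clinical: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir) -> dict:
        """Write clinical/variants/truth TSVs; returns path → sha256 digest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (
            f"# tp53kit synthetic cohort | seed={self.config.seed} "
            f"n={self.config.n_patients}\n"
        )
        digests = {}
        for name, df in (("clinical.tsv", self.clinical),
                         ("variants.tsv", self.variants),
                         ("truth.tsv", self.truth)):
            path = outdir / name
            body = df.to_csv(sep="\t", index=False)
            path.write_text(header + body)
            digests[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()
        return digests


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort, deterministic given ``config.seed``."""
    config.validate()
    streams = dict(
        zip(_STREAMS, (np.random.default_rng(s)
                       for s in np.random.SeedSequence(config.seed).spawn(len(_STREAMS))))
    )
    rng_cov, rng_tp53 = streams["covariates"], streams["tp53"]
    rng_ea, rng_bg = streams["ea"], streams["background"]
    rng_surv, rng_cens = streams["survival"], streams["censoring"]

    n = config.n_patients
    seq = pseudo_protein_sequence()
    transcript = default_transcript_model()
    domains = default_domain_map()
    properties = default_property_table()
    ea_fixed = synthetic_ea_score_table()
    l2, l3 = domains.span("L2"), domains.span("L3")
    exon8 = next((a, b) for num, a, b in transcript.exons if num == 8)
    aas = list("ACDEFGHIKLMNPQRSTVWY")

    ids = [f"P{i + 1:04d}" for i in range(n)]

    # --- covariates ------------------------------------------------------
    age = np.clip(
        np.rint(rng_cov.normal(config.age_mean, config.age_sd, size=n)),
        *config.age_range,
    ).astype(int)
    sex = np.where(rng_cov.uniform(size=n) < config.male_prob, "male", "female")
    smoking = np.where(rng_cov.uniform(size=n) < config.smoker_prob,
                       "smoker", "nonsmoker")
    hist_labels, hist_p = zip(*config.histology_probs)
    histology = rng_cov.choice(hist_labels, size=n,
                               p=np.array(hist_p) / sum(hist_p))
    stage_labels, stage_p = zip(*config.stage_probs)
    stage = rng_cov.choice(stage_labels, size=n,
                           p=np.array(stage_p) / sum(stage_p))
    multi_met = np.where(
        stage == "IV",
        np.where(rng_cov.uniform(size=n) < config.multi_organ_met_prob, "yes", "no"),
        "not_applicable",
    )
    ici = rng_cov.uniform(size=n) < config.ici_treated_prob
    os_draw = rng_cov.uniform(size=n)  # drawn for everyone; applied later

    # --- TP53 variants ---------------------------------------------------
    templates, weights = zip(*config.spectrum)
    weights = np.array(weights) / np.sum(weights)
    mutant = rng_tp53.uniform(size=n) < config.tp53_prevalence

    def draw_ea(ref, pos, alt):
        fixed = ea_fixed.lookup(ref, pos, alt)
        if fixed is not None:
            return fixed
        if rng_ea.uniform() < config.ea_high_weight:
            raw = rng_ea.normal(config.ea_high_mean, config.ea_high_sd)
        else:
            raw = rng_ea.normal(config.ea_low_mean, config.ea_low_sd)
        return float(np.clip(raw, 0.0, 100.0))

    def make_variant(template: str) -> dict:
        """One TP53 variant row + its generative truth flags."""
        if template == "splice":
            return dict(protein_change="splice", classification="Splice_Site",
                        effect="splice", position=None, ea=None)
        if template in ("nonsense_flank", "frameshift_flank"):
            pos = int(rng_tp53.choice(_pool(_FLANK_RANGES)))
            ref = seq[pos - 1]
            if template == "nonsense_flank":
                return dict(protein_change=f"{ref}{pos}*",
                            classification="Nonsense_Mutation",
                            effect="nonsense", position=pos, ea=None)
            return dict(protein_change=f"{ref}{pos}fs",
                        classification="Frame_Shift_Del",
                        effect="frameshift", position=pos, ea=None)
        if template in ("missense_dbd", "missense_other"):
            ranges = _DBD_HOT_RANGES if template == "missense_dbd" else _NON_DBD_RANGES
            pos = int(rng_tp53.choice(_pool(ranges)))
            ref = seq[pos - 1]
            alt = str(rng_tp53.choice([a for a in aas if a != ref]))
            ea = draw_ea(ref, pos, alt)
            return dict(protein_change=f"{ref}{pos}{alt}",
                        classification="Missense_Mutation",
                        effect="missense", position=pos, ea=round(ea, 2))
        # fixed hotspot template like "R282W" / "E298X"
        ref, pos, alt = template[0], int(template[1:-1]), template[-1]
        if alt in ("X", "*"):
            return dict(protein_change=f"{ref}{pos}X",
                        classification="Nonsense_Mutation",
                        effect="nonsense", position=pos, ea=None)
        ea = draw_ea(ref, pos, alt)
        return dict(protein_change=template, classification="Missense_Mutation",
                    effect="missense", position=pos, ea=round(ea, 2))

    def in_span(pos, span):
        return pos is not None and span[0] <= pos <= span[1]

    variant_rows = []
    truth_rows = []
    hr_flags = np.zeros(n, dtype=bool)
    lp_parts = {k: np.zeros(n) for k in
                ("missense", "exon8", "nondisruptive", "eap53_high")}
    for i, pid in enumerate(ids):
        flags = dict(has_missense=False, has_truncating=False, has_exon8=False,
                     has_nondisruptive_missense=False, eap53_high=False,
                     eap53_low=False, n_tp53=0)
        if mutant[i]:
            k = 2 if rng_tp53.uniform() < config.multi_mutation_fraction else 1
            chosen = rng_tp53.choice(len(templates), size=k, p=weights)
            for c in chosen:
                v = make_variant(templates[int(c)])
                variant_rows.append(
                    dict(patient_id=pid, gene="TP53",
                         protein_change=v["protein_change"],
                         variant_classification=v["classification"],
                         ea_score=v["ea"])
                )
                flags["n_tp53"] += 1
                pos = v["position"]
                if v["effect"] == "missense":
                    flags["has_missense"] = True
                    in_loop = in_span(pos, l2) or in_span(pos, l3)
                    ref, alt = v["protein_change"][0], v["protein_change"][-1]
                    disruptive = in_loop and not properties.same_group(ref, alt)
                    if not disruptive:
                        flags["has_nondisruptive_missense"] = True
                    if v["ea"] is not None and v["ea"] > 75.0:
                        flags["eap53_high"] = True
                    elif v["ea"] is not None:
                        flags["eap53_low"] = True
                else:
                    flags["has_truncating"] = True
                if in_span(pos, exon8):
                    flags["has_exon8"] = True
        hr_flags[i] = flags["eap53_high"]
        lp_parts["missense"][i] = flags["has_missense"]
        lp_parts["exon8"][i] = flags["has_exon8"]
        lp_parts["nondisruptive"][i] = flags["has_nondisruptive_missense"]
        lp_parts["eap53_high"][i] = flags["eap53_high"]
        if flags["eap53_high"]:
            four = "EAp53 high-risk"
        elif flags["eap53_low"]:
            four = "EAp53 low-risk"
        elif flags["has_truncating"]:
            four = "truncating"
        elif flags["n_tp53"]:
            four = "other"
        else:
            four = "WT"
        truth_rows.append(dict(patient_id=pid, tp53_mutant=bool(mutant[i]),
                               four_group=four, **flags))

    # --- background genes + EGFR covariate -------------------------------
    genes = sorted(config.background_genes)
    egfr_mut = np.zeros(n, dtype=bool)
    for i, pid in enumerate(ids):
        p_idx = 0 if hr_flags[i] else 1
        for gene in genes:
            if rng_bg.uniform() < config.background_genes[gene][p_idx]:
                variant_rows.append(
                    dict(patient_id=pid, gene=gene, protein_change=None,
                         variant_classification="Missense_Mutation", ea_score=None)
                )
                if gene == "EGFR":
                    egfr_mut[i] = True
        lam = config.passenger_lambda_hr if hr_flags[i] else config.passenger_lambda_ot
        for _ in range(int(rng_bg.poisson(lam))):
            gene = str(rng_bg.choice(config.passenger_genes))
            silent = rng_bg.uniform() < config.passenger_silent_fraction
            variant_rows.append(
                dict(patient_id=pid, gene=gene, protein_change=None,
                     variant_classification="Silent" if silent else "Missense_Mutation",
                     ea_score=None)
            )

    # --- survival ---------------------------------------------------------
    b = config.log_hazard_ratios
    lp = (
        b.get("eap53_high", 0.0) * lp_parts["eap53_high"]
        + b.get("missense", 0.0) * lp_parts["missense"]
        + b.get("exon8", 0.0) * lp_parts["exon8"]
        + b.get("nondisruptive", 0.0) * lp_parts["nondisruptive"]
        + b.get("male", 0.0) * (sex == "male")
        + b.get("smoker", 0.0) * (smoking == "smoker")
        + b.get("age_gt65", 0.0) * (age > 65)
        + b.get("egfr_mutant", 0.0) * egfr_mut
    )
    u = rng_surv.uniform(size=n)
    t_event = config.weibull_scale_months * (
        -np.log(u) / np.exp(lp)
    ) ** (1.0 / config.weibull_shape)
    t_cens = (
        rng_cens.exponential(1.0 / config.censor_exp_rate, size=n)
        if config.censor_exp_rate > 0 else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_cens, config.censor_horizon_months)
    obs_time = np.maximum(np.round(np.minimum(t_event, t_cens), 2), 0.01)
    event = (t_event <= t_cens).astype(int)

    advanced = np.isin(stage, ["III", "IV"])
    os_avail = advanced & ~ici & (os_draw < config.os_available_prob)

    clinical = pd.DataFrame(
        dict(
            patient_id=ids, age_years=age, sex=sex, smoking=smoking,
            histology=histology, stage=stage, multi_organ_met=multi_met,
            egfr_status=np.where(egfr_mut, "mutant", "wild_type"),
            os_months=np.where(os_avail, obs_time, np.nan),
            os_event=np.where(os_avail, event, np.nan),
            ici_treated=ici,
        )
    )
    variants = pd.DataFrame(
        variant_rows,
        columns=["patient_id", "gene", "protein_change",
                 "variant_classification", "ea_score"],
    )
    truth = pd.DataFrame(truth_rows)
    truth["egfr_mutant"] = egfr_mut
    truth["linear_predictor"] = np.round(lp, 6)
    truth["true_event_time"] = np.round(t_event, 4)
    truth["observed_time"] = obs_time
    truth["event"] = event
    truth["os_available"] = os_avail
    return SimulatedCohort(clinical=clinical, variants=variants, truth=truth,
                           config=config)
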