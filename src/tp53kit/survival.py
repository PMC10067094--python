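"""Kaplan–Meier estimation, log-rank comparison and Cox proportional-hazards
modelling over stratified cohorts.

The estimators are the standard ones (product-limit curve, k-group log-rank
with a chi-square reference on k−1 df, Cox partial likelihood with Efron or
Breslow tie handling); this module wraps them behind a cohort-aware surface
and assembles the full per-scheme analysis: sub-comparisons against wild
type, the combined two-group contrast, univariate Cox, and one multivariate
Cox adjusting for age>65, sex, smoking and EGFR status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .cohort import Cohort, aggregate_patient_tp53, apply_cohort_filters
from .exceptions import ValidationError
from .stratify import stratify

DEFAULT_ADJUSTMENT = ("age_gt65", "sex_male", "smoker", "egfr_mutant")

FOUR_GROUP_ORDER = ("EAp53 high-risk", "EAp53 low-risk", "truncating", "other")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: survival probability at each event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censored: np.ndarray  # number censored at each time

    def __post_init__(self):
        s = self.survival
        if len(s) and (s.max() > 1.0 + 1e-12 or s.min() < -1e-12):
            raise ValidationError("survival probabilities must lie in [0,1]")
        if len(s) > 1 and (np.diff(s) > 1e-12).any():
            raise ValidationError("survival curve must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t); S(t)=1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time=self.times, survival=self.survival,
                 at_risk=self.at_risk, censored=self.censored)
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    Censoring at an event time is processed after the events at that time
    (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValidationError("need at least one observation")
    if (t <= 0).any():
        raise ValidationError("survival times must be positive")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # lifelines inserts a t=0 row with no events; keep observed times only
    table = kmf.event_table[kmf.event_table.index > 0]
    sf = kmf.survival_function_["KM_estimate"]
    times_out = table.index.to_numpy(dtype=float)
    surv = np.array([float(sf.loc[u]) for u in times_out])
    return SurvivalCurve(
        times=times_out,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: dict


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test with a chi-square reference on k−1 df."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if (t <= 0).any():
        raise ValidationError("survival times must be positive")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("log-rank needs at least two non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(len(labels) - 1),
        p_value=float(res.p_value),
        group_sizes={str(l): int(c) for l, c in zip(labels, counts)},
    )


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    terms: pd.DataFrame  # covariate, coef, se, hr, ci_low, ci_high, p_value
    n: int
    n_events: int
    ties: str
    converged: bool

    def hr(self, covariate: str) -> float:
        return float(self.terms.set_index("covariate").loc[covariate, "hr"])


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit via partial likelihood.

    ``ties`` is ``"efron"`` (default, better with monthly-resolution ties) or
    ``"breslow"``. Rows with missing values in any used column are dropped.
    Constant covariates and under-determined designs raise
    :class:`ValidationError`; non-convergence is flagged on the result, not
    raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    cols = [duration_col, event_col, *covariates]
    df = data[cols].dropna()
    if (df[duration_col] <= 0).any():
        raise ValidationError("survival times must be positive")
    n_events = int(df[event_col].sum())
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValidationError(f"covariate {c!r} is constant across subjects")
    if n_events < len(covariates):
        raise ValidationError(
            f"{n_events} events cannot identify {len(covariates)} covariates"
        )
    X = df[list(covariates)].astype(float).to_numpy()
    model = PHReg(
        df[duration_col].to_numpy(dtype=float),
        X,
        status=df[event_col].to_numpy(dtype=int),
        ties=ties,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False)
        except Exception:
            try:
                res = model.fit(method="bfgs", disp=False)
            except Exception as exc:  # pragma: no cover - pathological designs
                raise ValidationError(f"Cox fit failed: {exc}") from exc
    coefs = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    if not (np.isfinite(coefs).all() and np.isfinite(ses).all()):
        converged = False
    z = 1.959963984540054  # Phi^{-1}(0.975)
    terms = pd.DataFrame(
        dict(
            covariate=list(covariates),
            coef=coefs,
            se=ses,
            hr=np.exp(coefs),
            ci_low=np.exp(coefs - z * ses),
            ci_high=np.exp(coefs + z * ses),
            p_value=np.asarray(res.pvalues, dtype=float),
        )
    )
    return CoxFit(terms=terms, n=len(df), n_events=n_events, ties=ties,
                  converged=converged)


def _survival_frame(cohort: Cohort) -> pd.DataFrame:
    clin = cohort.clinical
    df = pd.DataFrame(
        dict(
            patient_id=clin["patient_id"],
            time=clin["os_months"].astype(float),
            event=clin["os_event"].astype(float),
            age_gt65=(clin["age_years"] > 65).astype(float),
        )
    )
    df["sex_male"] = np.where(
        clin["sex"] == "unknown", np.nan, (clin["sex"] == "male").astype(float)
    )
    df["smoker"] = np.where(
        clin["smoking"] == "unknown", np.nan, (clin["smoking"] == "smoker").astype(float)
    )
    df["egfr_mutant"] = np.where(
        clin["egfr_status"] == "unknown",
        np.nan,
        (clin["egfr_status"] == "mutant").astype(float),
    )
    return df.set_index("patient_id")


def _safe_logrank(sub: pd.DataFrame) -> Optional[dict]:
    if sub["group"].nunique() < 2 or len(sub) < 2:
        return None
    res = logrank_test(sub["time"], sub["event"].astype(int), sub["group"])
    return dict(statistic=res.statistic, df=res.df, p_value=res.p_value,
                group_sizes=res.group_sizes)


def _cox_block(df: pd.DataFrame, indicators: list[str], adjust: Sequence[str],
               ties: str) -> dict:
    block = {}
    for label, covs in (("univariate", indicators),
                        ("multivariate", indicators + list(adjust))):
        try:
            fit = cox_fit(df, "time", "event", covs, ties=ties)
            block[label] = dict(
                terms=fit.terms.to_dict(orient="records"),
                n=fit.n, n_events=fit.n_events, ties=fit.ties,
                converged=fit.converged,
            )
        except ValidationError as exc:
            block[label] = dict(error=str(exc))
    return block


def run_survival_analysis(
    cohort: Cohort,
    schemes: Sequence[str] = ("missense_vs_others", "nondisruptive_vs_others",
                              "exon8_vs_others", "eap53_vs_others", "four_group"),
    adjust_for: Sequence[str] = DEFAULT_ADJUSTMENT,
    ties: str = "efron",
    apply_filters: bool = True,
) -> dict:
    """Full survival analysis over the requested stratification schemes.

    For each scheme: Kaplan–Meier curves per group, the pre-combination
    sub-comparisons against wild type, the combined contrast (log-rank),
    a univariate Cox fit of the scheme indicator(s), and one multivariate
    Cox fit adjusting for ``adjust_for``. Advanced-stage / ICI-naive / OS
    filters are applied first unless ``apply_filters`` is False.
    """
    report: dict = {}
    if apply_filters:
        cohort, filter_report = apply_cohort_filters(
            cohort, require_stage_advanced=True, require_ici_naive=True, require_os=True
        )
        report["filter_report"] = filter_report
    status = aggregate_patient_tp53(cohort)
    surv = _survival_frame(cohort)
    report["n"] = int(len(surv))
    report["schemes"] = {}

    for scheme in schemes:
        labels = stratify(status, scheme)
        df = surv.join(labels.rename("group"))
        present = df["group"].value_counts()
        entry: dict = {"group_sizes": {str(k): int(v) for k, v in present.items()}}
        if len(present) < 2:
            warnings.warn(f"scheme {scheme}: fewer than two groups after filtering; skipped",
                          stacklevel=2)
            entry["skipped"] = "fewer than two groups"
            report["schemes"][scheme] = entry
            continue

        entry["km"] = {
            str(g): km_estimate(sub["time"], sub["event"].astype(int)).to_frame().to_dict(orient="list")
            for g, sub in df.groupby("group")
        }
        entry["logrank"] = _safe_logrank(df)

        wt_ids = status.index[status["wild_type"]]
        if scheme != "four_group":
            positive = next(l for l in df["group"].unique() if l != "others")
            pos_ids = labels.index[labels == positive]
            comp_ids = status.index[status["has_mutation"] & (labels != positive)]
            subs = {}
            for name, ids in ((f"{positive}_vs_WT", pos_ids),
                              ("other_mutant_vs_WT", comp_ids)):
                sub = df.loc[df.index.isin(set(ids) | set(wt_ids))].copy()
                sub["group"] = np.where(sub.index.isin(set(wt_ids)), "WT", "mutant")
                subs[name] = _safe_logrank(sub)
            entry["sub_comparisons"] = subs
            df["exposed"] = (df["group"] == positive).astype(float)
            entry["cox"] = _cox_block(df, ["exposed"], adjust_for, ties)
        else:
            subs = {}
            for g in FOUR_GROUP_ORDER:
                ids = labels.index[labels == g]
                if len(ids) == 0:
                    continue
                sub = df.loc[df.index.isin(set(ids) | set(wt_ids))]
                subs[f"{g}_vs_WT"] = _safe_logrank(sub)
            entry["sub_comparisons"] = subs
            indicators = []
            for g in FOUR_GROUP_ORDER:
                col = f"is_{g.replace(' ', '_').replace('-', '_')}"
                vals = (df["group"] == g).astype(float)
                if vals.sum() > 0:
                    df[col] = vals
                    indicators.append(col)
            entry["cox"] = _cox_block(df, indicators, adjust_for, ties)
        report["schemes"][scheme] = entry
    return report
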