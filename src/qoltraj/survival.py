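"""Landmark survival machinery: Kaplan-Meier, log-rank, Cox, Harrell's C.

Estimation is delegated to lifelines; this module supplies the landmark
conditioning (subjects must still be at risk at the landmark, times are
re-origined there) and typed result containers.  The landmark guards the
trajectory-derived groupings against immortal-time bias: a class defined by
16 weeks of QoL must only be compared on survival beyond 16 weeks.

Survival time is in months; landmarks are stated in weeks and converted at
4.348 weeks per month by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

from .data import SurvivalData, ValidationError

WEEKS_PER_MONTH = 4.348


class EmptyRiskSetError(ValidationError):
    """The landmark exceeds every follow-up time."""


@dataclass
class LandmarkResult:
    """Survivors of the landmark with re-origined times."""

    data: SurvivalData
    n_excluded: int
    landmark_weeks: float
    landmark_months: float


def landmark_filter(
    surv: SurvivalData,
    landmark_weeks: float,
    weeks_per_month: float = WEEKS_PER_MONTH,
) -> LandmarkResult:
    """Condition on being at risk at the landmark.

    Subjects whose event or censoring falls strictly before the landmark are
    excluded (the count is reported); events exactly at the landmark are
    retained with a vanishing residual time.
    """
    if landmark_weeks < 0:
        raise ValidationError("landmark must be non-negative")
    lm = landmark_weeks / weeks_per_month
    keep = surv.time >= lm
    n_excl = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyRiskSetError(f"no subject at risk at landmark {landmark_weeks} weeks")
    ids = [s for s, k in zip(surv.subject_ids, keep) if k]
    time = np.maximum(surv.time[keep] - lm, 1e-9)
    cov = None if surv.covariates is None else surv.covariates.loc[ids].copy()
    out = SurvivalData(ids, time, surv.event[keep].copy(), cov)
    return LandmarkResult(out, n_excl, landmark_weeks, lm)


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and log-log CI."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    variance: np.ndarray  # Greenwood
    ci_low: np.ndarray
    ci_high: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.timeline,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "greenwood_var": self.variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def km_estimate(surv: SurvivalData, label: str = "") -> KMCurve:
    """Kaplan-Meier estimate (lifelines) with Greenwood variance."""
    if surv.n_subjects < 1:
        raise ValidationError("need at least one subject")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(surv.time, surv.event, label="S")
    tab = kmf.event_table
    timeline = tab.index.to_numpy(dtype=float)
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    events = tab["observed"].to_numpy(dtype=float)
    censored = tab["censored"].to_numpy(dtype=float)
    surv_prob = kmf.survival_function_.reindex(timeline)["S"].to_numpy()
    # Greenwood: Var(S(t)) = S(t)^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(at_risk > events, events / (at_risk * (at_risk - events)), 0.0)
    var = surv_prob**2 * np.cumsum(incr)
    ci = kmf.confidence_interval_.reindex(timeline).to_numpy()
    return KMCurve(
        timeline=timeline,
        survival=surv_prob,
        at_risk=at_risk,
        events=events,
        censored=censored,
        variance=var,
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        label=label,
    )


def logrank_test(surv: SurvivalData, groups) -> tuple[float, int, float]:
    """G-sample log-rank test; returns (chi-square, df, p)."""
    groups = np.asarray(groups)
    if groups.shape != (surv.n_subjects,):
        raise ValidationError("group labels must align with subjects")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(surv.time, groups, surv.event)
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit with Wald inference and Harrell's C."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_low: pd.Series  # on the HR scale
    ci_high: pd.Series
    p_values: pd.Series
    partial_loglik: float
    c_index: float
    n_subjects: int
    n_events: int
    ties: str
    _fitter: object = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. monotone likelihood)."""


def cox_fit(surv: SurvivalData, covariates: pd.DataFrame, ties: str = "efron") -> CoxFit:
    """Cox PH partial-likelihood fit on the given covariate matrix.

    ``ties`` is ``"efron"`` (default, better with heavy month-resolution
    ties) or ``"breslow"``.  Constant covariates are rejected as
    non-identifiable; monotone likelihood (perfect separation) surfaces as
    :class:`CoxConvergenceError`.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError("ties must be 'efron' or 'breslow'")
    cov = covariates.copy()
    if list(cov.index) != list(surv.subject_ids):
        cov = cov.reindex(surv.subject_ids)
    if cov.isna().any().any():
        raise ValidationError("covariate matrix has missing values or unknown subjects")
    if not np.isfinite(cov.to_numpy(float)).all():
        raise ValidationError("covariates must be finite")
    if surv.event.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    const = [c for c in cov.columns if np.ptp(cov[c].to_numpy(float)) == 0]
    if const:
        raise ValidationError(f"constant covariate(s) not identifiable: {const}")

    from statsmodels.duration.hazard_regression import PHReg

    X = cov.to_numpy(float)
    model = PHReg(surv.time, X, status=surv.event, ties=ties)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:
            raise CoxConvergenceError(str(exc)) from exc
    params = np.asarray(res.params)
    if not np.isfinite(params).all() or np.abs(params).max() > 50:
        raise CoxConvergenceError("diverging coefficients suggest monotone partial likelihood")
    se = np.asarray(res.bse)
    from scipy.stats import norm

    zcrit = norm.ppf(0.975)
    pvals = 2 * norm.sf(np.abs(params / se))
    names = list(cov.columns)
    risk = X @ params
    return CoxFit(
        coefficients=pd.Series(params, index=names),
        hazard_ratios=pd.Series(np.exp(params), index=names),
        ci_low=pd.Series(np.exp(params - zcrit * se), index=names),
        ci_high=pd.Series(np.exp(params + zcrit * se), index=names),
        p_values=pd.Series(pvals, index=names),
        partial_loglik=float(model.loglike(params)),
        c_index=float(concordance_index(surv.time, -risk, surv.event)),
        n_subjects=surv.n_subjects,
        n_events=int(surv.event.sum()),
        ties=ties,
        _fitter=res,
    )


def c_index(risk_scores, surv: SurvivalData) -> float:
    """Harrell's C for risk scores (higher score = higher hazard).

    Concordant usable pairs / usable pairs, score ties counted 1/2; pairs
    whose ordering censoring leaves undetermined are excluded.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if risk.shape != (surv.n_subjects,):
        raise ValidationError("risk scores must align with subjects")
    if surv.event.sum() == 0:
        raise ValidationError("C-index undefined without any usable (event) pair")
    try:
        return float(concordance_index(surv.time, -risk, surv.event))
    except ZeroDivisionError as exc:
        raise ValidationError("C-index undefined: no usable pairs") from exc
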