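"""Synthetic-cohort generator for the trajectory-clustering pipeline.

Emulates a two-arm trial of ~360 patients per arm whose global QoL score is
measured at weeks 0, 2, 4, 6, 8, 12, 16 and whose survival depends on the
latent trajectory.  The generating model mirrors the analysis model:

* latent class ``C`` drawn from a multinomial logit (optionally
  covariate-dependent),
* subject growth factors ``eta0`` (intercept) and ``eta1`` (linear slope,
  per week) = class mean + bivariate-normal random effect; the quadratic
  term is a class-level fixed effect,
* observed score ``y_t = eta0 + eta1*t + beta2_k*t^2 + gamma'x + eps_t``
  with iid Gaussian residuals,
* monotone missing-at-random dropout whose per-visit hazard is logistic in
  the previous observed score,
* Weibull survival with log-hazard linear in the subject's true
  (baseline, slope, quadratic), plus uniform administrative censoring.

Because dropout depends only on previously observed values, the missingness
is MAR by construction, matching the assumption that licenses
full-information maximum likelihood downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import DEFAULT_VISIT_WEEKS, QoLPanel, SurvivalData, ValidationError


def _sigmoid(x):
    with np.errstate(over="ignore"):  # extreme logits saturate cleanly
        return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class DropoutSpec:
    """Per-visit dropout hazard, logistic in the previous observed score.

    ``P(drop at visit j | observed at j-1) = sigmoid(intercept +
    per_point * (previous score - center))``.  Baseline is never dropped;
    once a visit is missed all later visits are missed (monotone).
    """

    intercept: float = -2.2
    per_point: float = -0.03
    center: float = 50.0

    def hazard(self, prev_score: np.ndarray) -> np.ndarray:
        return _sigmoid(self.intercept + self.per_point * (np.asarray(prev_score) - self.center))


@dataclass(frozen=True)
class HazardLink:
    """Weibull survival with log-hazard linear in the true growth factors.

    ``log HR = log_hr_baseline*(eta0 - center_baseline) + log_hr_slope*eta1
    + log_hr_quad*beta2``.  ``scale_months`` is the Weibull scale at log-HR
    zero; ``shape`` the Weibull shape.  Censoring is uniform on
    ``censor_months``.
    """

    log_hr_baseline: float = float(np.log(0.98))
    log_hr_slope: float = float(np.log(0.87))
    log_hr_quad: float = float(np.log(0.46))
    center_baseline: float = 60.0
    scale_months: float = 12.0
    shape: float = 1.2
    censor_months: tuple[float, float] = (18.0, 42.0)

    def linear_predictor(self, baseline, slope, quad) -> np.ndarray:
        return (
            self.log_hr_baseline * (np.asarray(baseline) - self.center_baseline)
            + self.log_hr_slope * np.asarray(slope)
            + self.log_hr_quad * np.asarray(quad)
        )


@dataclass(frozen=True)
class CovariateDists:
    """Sampling frequencies for the baseline covariates."""

    p_male: float = 0.64
    ecog_probs: tuple[float, float, float] = (0.32, 0.58, 0.10)
    age_mean: float = 63.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (27.0, 85.0)
    p_experimental: float = 0.5


@dataclass(frozen=True)
class SimScenario:
    """Full generating model for one synthetic cohort.

    ``class_growth_means`` is (K, 3): per-class (baseline, slope per week,
    quadratic per week^2).  ``class_logit_coefs`` is (K, 3): multinomial
    logit coefficients on (1, male, ecog) relative to nothing (softmax over
    rows); intercept-only rows give fixed class proportions.
    ``covariate_effects`` are additive shifts of the QoL level (equivalently
    of the latent intercept) for male sex and each ECOG level above 0.
    """

    n_subjects: int = 360
    class_growth_means: tuple = ((73.0, -0.3, 0.0), (38.0, 1.0, -0.08), (55.0, -2.2, 0.10))
    class_logit_coefs: tuple | None = None  # default: intercepts from class_probs
    class_probs: tuple = (0.64, 0.18, 0.18)
    covariate_effects: tuple = (("male", 4.0), ("ecog1", -8.0), ("ecog2", -17.0))
    re_cov: tuple = ((25.0, 0.0), (0.0, 0.04))
    resid_sd: float = 6.0
    dropout: DropoutSpec | None = DropoutSpec()
    hazard_link: HazardLink = HazardLink()
    covariate_dists: CovariateDists = CovariateDists()
    visit_weeks: tuple = DEFAULT_VISIT_WEEKS
    clamp_scores: bool = True
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_growth_means)

    def validate(self) -> None:
        re_cov = np.asarray(self.re_cov, dtype=float)
        if re_cov.shape != (2, 2) or not np.allclose(re_cov, re_cov.T):
            raise ValidationError("re_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(re_cov).min() < -1e-10:
            raise ValidationError("re_cov must be positive semi-definite")
        if self.resid_sd < 0:
            raise ValidationError("resid_sd must be non-negative")
        if self.hazard_link.scale_months <= 0 or self.hazard_link.shape <= 0:
            raise ValidationError("Weibull scale and shape must be positive")
        if self.class_logit_coefs is None:
            probs = np.asarray(self.class_probs, dtype=float)
            if probs.shape != (self.n_classes,) or abs(probs.sum() - 1.0) > 1e-8:
                raise ValidationError("class_probs must sum to 1, one per class")

    def logit_coef_matrix(self) -> np.ndarray:
        """(K, 3) logit coefficients on (1, male, ecog)."""
        if self.class_logit_coefs is not None:
            coefs = np.asarray(self.class_logit_coefs, dtype=float)
            if coefs.shape != (self.n_classes, 3):
                raise ValidationError("class_logit_coefs must have shape (K, 3)")
            return coefs
        coefs = np.zeros((self.n_classes, 3))
        coefs[:, 0] = np.log(np.asarray(self.class_probs, dtype=float))
        return coefs


@dataclass
class SimulatedCohort:
    """One generated cohort with the latent truth kept alongside."""

    panel: QoLPanel
    survival: SurvivalData
    true_class: np.ndarray
    true_growth: np.ndarray  # (n, 2): subject intercept, slope per week
    true_quad: np.ndarray  # (n,): class quadratic fixed effect
    latent_scores: np.ndarray  # unclamped complete trajectories

    @property
    def latent_panel(self) -> QoLPanel:
        """Panel carrying unclamped scores with the observed-missingness mask."""
        scores = self.latent_scores.copy()
        scores[~self.panel.observed] = np.nan
        return QoLPanel(
            list(self.panel.subject_ids),
            self.panel.visit_weeks.copy(),
            scores,
            self.panel.covariates.copy(),
            validate_range=False,
        )


def default_scenario(**overrides) -> SimScenario:
    """Default cohort at the scale of one arm of a 750-patient trial."""
    return replace(SimScenario(), **overrides) if overrides else SimScenario()


def recovery_scenario(**overrides) -> SimScenario:
    """Well-separated three-class scenario used for parameter-recovery studies.

    Class baselines 75/55/35 with small random-effect and residual
    variability (intercept SD 3 against 20-point class gaps), so modal
    classification is nearly crisp and the generating parameters are
    identifiable at n of a few hundred.
    """
    base = SimScenario(
        n_subjects=600,
        class_growth_means=((75.0, -0.5, 0.0), (55.0, 0.3, -0.03), (35.0, -1.0, 0.05)),
        class_probs=(0.45, 0.35, 0.20),
        re_cov=((9.0, 0.0), (0.0, 0.0225)),
        resid_sd=5.0,
    )
    return replace(base, **overrides) if overrides else base


def _draw_covariates(rng: np.random.Generator, scn: SimScenario) -> pd.DataFrame:
    d = scn.covariate_dists
    n = scn.n_subjects
    sex = np.where(rng.random(n) < d.p_male, "male", "female")
    ecog = rng.choice([0, 1, 2], size=n, p=np.asarray(d.ecog_probs) / np.sum(d.ecog_probs))
    age = np.clip(rng.normal(d.age_mean, d.age_sd, n), *d.age_bounds)
    arm = np.where(rng.random(n) < d.p_experimental, "experimental", "standard")
    ids = [f"S{i+1:04d}" for i in range(n)]
    return pd.DataFrame({"sex": sex, "ecog": ecog, "age": age, "arm": arm}, index=ids)


def _covariate_shift(cov: pd.DataFrame, effects) -> np.ndarray:
    shift = np.zeros(len(cov))
    eff = dict(effects)
    shift += np.where(cov["sex"].to_numpy() == "male", eff.get("male", 0.0), 0.0)
    shift += np.where(cov["ecog"].to_numpy() == 1, eff.get("ecog1", 0.0), 0.0)
    shift += np.where(cov["ecog"].to_numpy() == 2, eff.get("ecog2", 0.0), 0.0)
    return shift


def simulate_cohort(scenario: SimScenario, seed: int | None = None) -> SimulatedCohort:
    """Generate one cohort under ``scenario``; ``seed`` overrides the scenario seed."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n, weeks = scenario.n_subjects, np.asarray(scenario.visit_weeks, dtype=float)
    cov = _draw_covariates(rng, scenario)

    # class membership from the multinomial logit on (1, male, ecog)
    X_class = np.column_stack(
        [np.ones(n), (cov["sex"] == "male").to_numpy(float), cov["ecog"].to_numpy(float)]
    )
    logits = X_class @ scenario.logit_coef_matrix().T
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    true_class = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)

    means = np.asarray(scenario.class_growth_means, dtype=float)
    re_cov = np.asarray(scenario.re_cov, dtype=float)
    vals, vecs = np.linalg.eigh(re_cov)  # PSD factor works at zero variance too
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    b = rng.standard_normal((n, 2)) @ factor.T
    shift = _covariate_shift(cov, scenario.covariate_effects)
    eta0 = means[true_class, 0] + shift + b[:, 0]
    eta1 = means[true_class, 1] + b[:, 1]
    quad = means[true_class, 2]

    latent = (
        eta0[:, None]
        + eta1[:, None] * weeks[None, :]
        + quad[:, None] * weeks[None, :] ** 2
        + rng.normal(0.0, scenario.resid_sd, size=(n, len(weeks)))
    )
    reported = np.clip(latent, 0.0, 100.0) if scenario.clamp_scores else latent.copy()

    panel = QoLPanel(
        list(cov.index), weeks, reported, cov, validate_range=scenario.clamp_scores
    )
    if scenario.dropout is not None:
        panel = apply_mar_dropout(panel, scenario.dropout, rng=rng)

    # Weibull survival via inverse transform, censored administratively
    hl = scenario.hazard_link
    lp = hl.linear_predictor(eta0, eta1, quad)
    uu = rng.random(n)
    t_event = hl.scale_months * (-np.log(uu) * np.exp(-lp)) ** (1.0 / hl.shape)
    c_lo, c_hi = hl.censor_months
    t_cens = rng.uniform(c_lo, c_hi, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = SurvivalData(list(cov.index), time, event, cov.copy())

    return SimulatedCohort(
        panel=panel,
        survival=survival,
        true_class=true_class,
        true_growth=np.column_stack([eta0, eta1]),
        true_quad=quad,
        latent_scores=latent,
    )


def apply_mar_dropout(
    panel: QoLPanel,
    dropout: DropoutSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> QoLPanel:
    """Apply monotone MAR dropout to a panel.

    Baseline is never removed; from each visit onward, a subject still under
    observation drops with the logistic hazard evaluated at their previous
    observed score, and stays missing thereafter.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    scores = panel.scores.copy()
    n, m = scores.shape
    alive = ~np.isnan(scores[:, 0])  # all True by panel invariant
    prev = scores[:, 0].copy()
    for j in range(1, m):
        p = dropout.hazard(prev)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("dropout probability outside [0, 1]")
        drop = rng.random(n) < p
        alive = alive & ~drop
        scores[~alive, j] = np.nan
        still = alive & ~np.isnan(scores[:, j])
        prev = np.where(still, scores[:, j], prev)
        # a visit missing for other reasons keeps the subject at risk with
        # the last observed score driving the next hazard
    return QoLPanel(
        list(panel.subject_ids),
        panel.visit_weeks.copy(),
        scores,
        panel.covariates.copy(),
        validate_range=panel.validate_range,
    )
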