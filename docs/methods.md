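# Methods

## The model

`qoltraj` clusters patients by the trajectory of a 0–100 quality-of-life
(QoL) score measured on a fixed visit grid — by default weeks 0, 2, 4, 6,
8, 12, 16, the assessment schedule of a 16-week systemic-therapy protocol —
and links the resulting latent classes and per-subject growth factors to
overall survival.

The core is a conditional quadratic growth mixture model.  Subject *i*
belongs to latent class *k* with probability π_k (optionally a multinomial
logit on covariates).  Given the class, the score at week *t* is

    y_it = β0_k + β1_k·t + β2_k·t² + γ'x_i + b0_i + b1_i·t + ε_it

with

* class-specific fixed growth means (β0_k, β1_k, β2_k): baseline, slope
  per week, quadratic per week²;
* covariates x_i (by default the screened ones, sex and ECOG performance
  status) shifting the trajectory level identically in every class;
* a bivariate normal random intercept/slope (b0, b1) ~ N(0, Ψ), shared
  across classes by default (`covariance_mode="class"` estimates Ψ_k and
  σ²_k per class);
* iid Gaussian residuals ε ~ N(0, σ²).

The quadratic is a class-level fixed effect with no random counterpart:
two latent continuous growth factors (intercept, slope) describe
between-subject variation, and the curvature belongs to the class shape.
This keeps the per-subject covariance structure rank-2 and the model
estimable at a few hundred subjects per arm.

### Missing data

Dropout is handled by full-information maximum likelihood: each subject
contributes the multivariate-normal density of their *observed* visits
only, i.e. the marginal of the dense ΛΨΛ' + σ²I covariance restricted to
observed rows and columns.  This is valid when missingness is at random
(MAR) — missingness may depend on anything observed, including earlier
scores, but not on the unobserved ones.  Intermittently missing visits are
handled identically; only a non-missing baseline is required (subjects
without one are excluded and counted by the readers).

### Estimation

EM treats the pair (class label, random effects) as missing data.  The
E-step computes class posteriors p_ik and conditional random-effect
moments; the M-step updates class weights, growth means and covariate
coefficients (a weighted least-squares solve against the random-effect
residual), and the variance components, all in closed form.  Because every
step maximizes the expected complete-data log-likelihood, the observed-data
log-likelihood is non-decreasing by construction; the per-iteration trace
is stored on every fit and asserted in the test suite.

Numerical choices:

* **Time coding.** Weeks are divided by 10 internally so the quadratic
  design (1, t, t²) is well-conditioned; every reported quantity is
  back-transformed to per-week units.  The same rescaling is applied inside
  the linear-mixed-model screen — without it the underlying optimizer can
  stall visibly short of the optimum on the raw week/week² design.
* **Starts.** Multi-start EM (default 20).  The first start clusters
  per-subject least-squares growth coefficients (intercept/slope only —
  per-subject quadratic estimates are too noisy) by k-means *after
  removing a pooled-OLS estimate of the covariate effects*; without that
  de-confounding, an ECOG-2 shift of −17 points makes a high-class patient
  look like a low-class one and k-means initializes in the wrong basin.
  Subsequent starts perturb the class means and occasionally shuffle a
  fifth of the initial labels.  Each start runs a short EM burst (40
  iterations); the best is run to convergence.
* **Convergence.** Relative log-likelihood change below 1e-6 (default),
  max 500 iterations.
* **Floors.** σ² ≥ 1e-4 and Ψ eigenvalues ≥ 1e-6 guard against the
  degenerate likelihood spikes endemic to Gaussian mixtures.  A tiny ridge
  (1e-10 of the mean diagonal) stabilizes the fixed-effect solve when a
  class weight collapses; collapsed classes (weight < 1/n) are flagged on
  the fit.
* **Label switching.** Classes are relabeled in descending model-implied
  baseline mean after every fit, so class 1 is always the best-baseline
  class and output order is stable across seeds on separated data.

### Model selection and diagnostics

The number of classes is chosen by BIC (−2·loglik + p·ln n, with n =
subjects, the mixture-model convention) over a K range, restricted to
candidates whose modal class proportions are all ≥ 10% and whose relative
entropy

    E = 1 − Σ_ik (−p_ik ln p_ik) / (n ln K)

reaches a configurable floor (default 0.7; the rule can be disabled, since
borderline values are routinely accepted in practice).  If no candidate is
admissible the unconstrained BIC minimizer is returned with a flag.  Nested
models with the same K are compared by the likelihood-ratio chi-square
test.

Per-subject growth factors are posterior-weighted empirical-Bayes
conditional means: baseline and slope are Σ_k p_ik·E[η | y_i, class k]
(the standard normal-conditioning formula on the observed visits, including
the covariate shift), and the quadratic is the posterior-weighted class
fixed effect.

## Covariate screen

A linear mixed model (`y ~ time (+ time²) + covariates`, random intercept
or intercept+slope, ML not REML) screens candidate covariates; backward
elimination drops the least significant block (categorical covariates as
whole blocks, via a joint Wald chi-square) until all remaining blocks are
below α = 0.05.  ML is the default so a one-class mixture reproduces the
screen's maximized log-likelihood exactly (verified to ~1e-8 in the tests).
Inference is Wald-z; no small-sample degrees-of-freedom correction is
applied, which is immaterial at several hundred subjects.  The default
screen uses a random intercept and linear fixed time; when the data carry a
random slope, pass `random_structure="intercept+slope"` — the
intercept-only screen is anti-conservative for between-subject covariates
in that case (visible in the null-covariate simulations).

## Survival linkage

All class-versus-survival comparisons are **landmark** analyses: subjects
whose event or censoring precedes the landmark (default week 16, the last
QoL visit; week 8 for the sensitivity run) are excluded and the count
reported, and times are re-origined at the landmark.  A class defined by 16
weeks of QoL data must not be credited with survival during those 16 weeks
— the landmark removes that immortal-time bias.  Events exactly at the
landmark are retained with a vanishing residual time (the boundary rule is
a package convention).  Survival time is in months; landmarks in weeks are
converted at 4.348 weeks/month (configurable).

Kaplan–Meier estimation, the G-sample log-rank test, Cox proportional
hazards (Efron tie handling by default, Breslow selectable) and Harrell's
C-index are delegated to lifelines/statsmodels behind typed wrappers;
Greenwood variances are accumulated from the event table.  The pipeline
fits two Cox models per arm: class indicators adjusted for sex and ECOG
(reporting Harrell's C), and the three per-subject growth factors
(baseline, slope, quadratic), optionally with an arm indicator when arms
are pooled.  Constant columns (e.g. the quadratic under K=1) are dropped
with a notice.

## The synthetic-cohort generator

No public release of the motivating trial's data exists, so every stage is
exercised on synthetic cohorts whose generating model mirrors the analysis
model: covariates (sex 64% male; ECOG 0/1/2 at 32/58/10%; age ~ N(63, 10);
1:1 arms), class from a multinomial logit, growth factors from the class
mean plus bivariate-normal random effects, covariate shifts of +4 (male),
−8 (ECOG 1), −17 (ECOG 2) points, Gaussian residuals, monotone MAR dropout
whose per-visit hazard is logistic in the previous observed score (≈10%
per visit at a score of 50, rising as scores fall; ~22% of cells missing
by week 16), and Weibull survival (shape 1.2, scale 12 months) whose
log-hazard is linear in the subject's *true* baseline/slope/quadratic with
hazard ratios 0.98 per baseline point, 0.87 per slope unit, 0.46 per
quadratic unit, under uniform 18–42-month administrative censoring.
Survival hangs off the true growth factors, not the observed scores, so
parameter-recovery and coverage tests have a well-defined target.

Two shipped calibrations:

* **`default_scenario`** (default; n=360, one arm's scale): three classes
  with baselines 73/38/55, slopes −0.3/+1.0/−2.2 per week, quadratics
  0/−0.08/+0.10 per week² (high-declining, low-concave, and
  intermediate-convex shapes), proportions 0.64/0.18/0.18, intercept SD 5,
  slope SD 0.2/week, residual SD 6.  This calibration was chosen so the
  diagnostics the analysis design presumes actually hold at n=360: BIC
  selects K=3, every modal class holds >10%, and entropy clears 0.7.  A
  mushier mixture (e.g. intercept SD 9) is *statistically undetectable* at
  this sample size — BIC correctly prefers K=2 even from a truth-started
  EM — and would make every downstream stage vacuous.  The cost is that
  fitted entropy lands around 0.85, crisper than the 0.69–0.75 typical of
  real QoL data; conclusions about borderline-entropy behavior should not
  be drawn from this scenario.
* **`recovery_scenario`** (n=600): baselines 75/55/35, residual SD 5,
  intercept SD 3, slope SD 0.15/week, proportions 0.45/0.35/0.20 — a
  deliberately well-separated calibration for parameter-recovery studies,
  where near-crisp classification is the point.

What the generator does **not** emulate: non-ignorable (MNAR) dropout,
visit-time jitter, floor/ceiling clustering of real questionnaire scores
beyond simple clamping (clamped and latent values are both returned; the
Gaussian likelihood is exercised on whichever the test needs), item-level
response behavior, and class-specific covariance heterogeneity.  Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to their violation.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use cohorts of 120–600 subjects,
20 EM starts for recovery studies and 5–12 elsewhere, 20 replicates for the
recovery and landmark-power properties, and 30–60 replicates for coverage
and type-I-error simulations (with correspondingly widened binomial
acceptance bands); these sizes make the full suite run in minutes while
keeping every binomial bound at a ≤1e-3 false-failure rate.

## Known limitations

* Exact r×c Fisher enumeration is attempted only while the branch count
  stays under 200k tables; beyond that a seeded Monte-Carlo p-value with
  fixed margins is returned (the report names the method used).
* The class-membership logit on covariates is supported but off by
  default; the default conditioning is the mean-shift pathway.
* No bootstrap likelihood-ratio test for K vs K−1; class enumeration rests
  on BIC plus the proportion/entropy rules.
* Monotone likelihood in the Cox fit (perfect separation) is reported as a
  convergence error rather than penalized.
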