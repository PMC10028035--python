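"""Linear mixed-effect screen for covariates associated with longitudinal QoL.

Fits ``y_it = beta' x_it + b_i' z_it + eps_it`` by maximum likelihood over
all non-missing visits (statsmodels MixedLM underneath) and screens
candidate covariates by backward elimination: categorical covariates are
dropped as whole blocks via a joint Wald chi-square test.  ML (not REML) is
the default so that the one-class growth mixture model with the same
mean/covariance structure attains the identical maximized log-likelihood;
inference is Wald z rather than a small-sample df correction, which is
immaterial at several hundred subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import QoLPanel, ValidationError
from .design import build_covariate_design


class SingularDesignError(ValidationError):
    """A covariate carries no variation (or is collinear) in the design."""


class LMMConvergenceError(RuntimeError):
    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class LMMFit:
    """Fixed effects with Wald inference plus variance components."""

    fixed_effects: pd.DataFrame  # coef, se, ci_low, ci_high, p
    block_pvalues: pd.Series  # joint Wald p per covariate block
    re_cov: np.ndarray  # random-effect covariance (1x1 or 2x2)
    resid_var: float
    loglik: float
    n_subjects: int
    n_observations: int
    converged: bool
    blocks: dict[str, list[str]]
    _result: object = None

    def __post_init__(self) -> None:
        if np.linalg.eigvalsh(self.re_cov).min() < -1e-8:
            raise ValidationError("random-effect covariance must be PSD")
        fe = self.fixed_effects
        if ((fe["ci_low"] > fe["coef"]) | (fe["ci_high"] < fe["coef"])).any():
            raise ValidationError("confidence bounds must bracket the estimate")


TIME_SCALE = 10.0  # weeks/10 internally; conditions the quadratic design


def _long_design(
    panel: QoLPanel, covariates, time_order: int
) -> tuple[pd.DataFrame, np.ndarray, list[str], dict[str, list[str]], np.ndarray]:
    long = panel.to_long()
    X, names, blocks = build_covariate_design(
        long[[c for c in panel.covariates.columns]], list(covariates)
    )
    w = long["week"].to_numpy(float) / TIME_SCALE
    cols = [np.ones(len(long)), w]
    colnames = ["intercept", "week"]
    unscale = [1.0, TIME_SCALE]
    if time_order == 2:
        cols.append(w**2)
        colnames.append("week^2")
        unscale.append(TIME_SCALE**2)
    unscale += [1.0] * len(names)
    design = np.column_stack(cols + ([X] if X.size else []))
    return long, design, colnames + names, blocks, np.asarray(unscale)


def fit_lmm(
    panel: QoLPanel,
    fixed_covariates=(),
    random_structure: str = "intercept",
    time_order: int = 1,
    reml: bool = False,
) -> LMMFit:
    """ML fit of the longitudinal model with the named fixed covariates.

    ``random_structure`` is ``"intercept"`` or ``"intercept+slope"``;
    ``time_order`` 1 (linear) or 2 (quadratic fixed time trend).
    """
    if panel.n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    if random_structure not in ("intercept", "intercept+slope"):
        raise ValidationError("random_structure must be 'intercept' or 'intercept+slope'")
    long, X, names, blocks, unscale = _long_design(panel, fixed_covariates, time_order)
    const_cols = [n for n, col in zip(names[1:], X.T[1:]) if np.ptp(col) == 0]
    if const_cols:
        raise SingularDesignError(f"constant design column(s): {const_cols}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("collinear fixed-effect design")

    groups = long["subject_id"].to_numpy()
    if random_structure == "intercept+slope":
        exog_re = np.column_stack(
            [np.ones(len(long)), long["week"].to_numpy(float) / TIME_SCALE]
        )
    else:
        exog_re = np.ones((len(long), 1))
    model = sm.MixedLM(long["qol"].to_numpy(float), X, groups=groups, exog_re=exog_re)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=reml, method=["lbfgs", "cg"], maxiter=500)
    except np.linalg.LinAlgError:
        # boundary case (subject variance ~ 0): the ML solution is plain OLS
        return _ols_fallback(long, X, names, blocks, unscale, panel, random_structure)
    if not result.converged:
        raise LMMConvergenceError("mixed model failed to converge", trace=result.summary())

    k = X.shape[1]
    coefs = np.asarray(result.fe_params) / unscale
    se = np.asarray(result.bse[:k]) / unscale
    ci = np.asarray(result.conf_int())[:k] / unscale[:, None]
    from scipy.stats import norm

    z = coefs / se
    pvals = 2 * norm.sf(np.abs(z))
    fe = pd.DataFrame(
        {"coef": coefs, "se": se, "ci_low": ci[:, 0], "ci_high": ci[:, 1], "p": pvals},
        index=names,
    )

    block_p = {}
    for cov, colnames in blocks.items():
        idx = [names.index(c) for c in colnames]
        R = np.zeros((len(idx), len(result.params)))
        for r, j in enumerate(idx):
            R[r, j] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = result.wald_test(R, scalar=True, use_f=False)
        block_p[cov] = float(wt.pvalue)
    resid_var = float(result.scale)
    re_cov = np.asarray(result.cov_re)  # already on the response scale
    if random_structure == "intercept+slope":  # back to per-week units
        s = np.array([[1.0, 1.0 / TIME_SCALE], [1.0 / TIME_SCALE, 1.0 / TIME_SCALE**2]])
        re_cov = re_cov * s
    return LMMFit(
        fixed_effects=fe,
        block_pvalues=pd.Series(block_p, dtype=float),
        re_cov=re_cov,
        resid_var=resid_var,
        loglik=float(result.llf),
        n_subjects=panel.n_subjects,
        n_observations=len(long),
        converged=bool(result.converged),
        blocks=blocks,
        _result=result,
    )


def _ols_fallback(long, X, names, blocks, unscale, panel, random_structure) -> LMMFit:
    """Degenerate mixed model (zero between-subject variance) -> pooled OLS."""
    from scipy.stats import norm

    res = sm.OLS(long["qol"].to_numpy(float), X).fit()
    coefs = np.asarray(res.params) / unscale
    se = np.asarray(res.bse) / unscale
    zcrit = norm.ppf(0.975)
    fe = pd.DataFrame(
        {
            "coef": coefs,
            "se": se,
            "ci_low": coefs - zcrit * se,
            "ci_high": coefs + zcrit * se,
            "p": 2 * norm.sf(np.abs(coefs / np.where(se > 0, se, np.inf))),
        },
        index=names,
    )
    block_p = {}
    for cov, colnames in blocks.items():
        idx = [names.index(c) for c in colnames]
        R = np.zeros((len(idx), len(res.params)))
        for r, j in enumerate(idx):
            R[r, j] = 1.0
        block_p[cov] = float(res.wald_test(R, use_f=False, scalar=True).pvalue)
    d = 1 if random_structure == "intercept" else 2
    return LMMFit(
        fixed_effects=fe,
        block_pvalues=pd.Series(block_p, dtype=float),
        re_cov=np.zeros((d, d)),
        resid_var=float(res.ssr / res.nobs),
        loglik=float(res.llf),
        n_subjects=panel.n_subjects,
        n_observations=len(long),
        converged=True,
        blocks=blocks,
        _result=res,
    )


def backward_eliminate(
    panel: QoLPanel,
    candidate_covariates,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[list[str], LMMFit | None]:
    """Backward elimination on the joint model at significance ``alpha``.

    Iteratively removes the covariate with the largest block Wald p-value at
    or above ``alpha``; stops when all remaining blocks are below ``alpha``.
    An empty candidate list returns an empty selection and no fit.
    """
    current = list(candidate_covariates)
    if not current:
        return [], None
    fit = fit_lmm(panel, current, **fit_kwargs)
    while current:
        pvals = fit.block_pvalues.loc[current]
        worst = pvals.idxmax()
        if pvals.loc[worst] < alpha:
            break
        current.remove(worst)
        if not current:
            return [], fit_lmm(panel, [], **fit_kwargs)
        fit = fit_lmm(panel, current, **fit_kwargs)
    return current, fit


def screening_report(
    panel: QoLPanel, candidates, alpha: float = 0.05, **fit_kwargs
) -> pd.DataFrame:
    """Univariable p per candidate plus the multivariable selection.

    Mirrors a screening table: one row per candidate with its univariable
    block p-value, a flag for surviving backward elimination, and the
    multivariable block p for survivors.
    """
    rows = []
    uva_p = {}
    for cov in candidates:
        f = fit_lmm(panel, [cov], **fit_kwargs)
        uva_p[cov] = float(f.block_pvalues[cov])
    selected, mva_fit = backward_eliminate(panel, candidates, alpha=alpha, **fit_kwargs)
    for cov in candidates:
        rows.append(
            {
                "covariate": cov,
                "uva_p": uva_p[cov],
                "selected": cov in selected,
                "mva_p": float(mva_fit.block_pvalues[cov]) if cov in selected else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
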