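"""Conditional quadratic growth mixture model estimated by EM with FIML.

The model: subject ``i`` belongs to latent class ``C_i = k`` with
probability ``pi_k`` (optionally a multinomial logit on covariates).  Given
class ``k``, the observed scores at weeks ``t`` are

    y_it = beta0_k + beta1_k * t + beta2_k * t^2 + gamma' x_i
           + b0_i + b1_i * t + eps_it

with bivariate-normal random intercept/slope ``(b0, b1) ~ N(0, Psi)`` and
iid residuals ``eps ~ N(0, sigma^2)``.  The quadratic term is a class-level
fixed effect; covariates shift the trajectory level within every class.

Missing visits are handled by full-information maximum likelihood: each
subject contributes the marginal multivariate-normal density of their
observed visits only, which is the marginalization of the dense
``Lambda Psi Lambda' + sigma^2 I`` covariance onto the observed rows and
columns — valid under missingness at random.

Estimation is EM with the pair (class label, random effects) treated as
missing data.  All M-steps are closed-form, so the observed-data
log-likelihood is non-decreasing by construction; the per-iteration trace is
stored on the fit and asserted in the test suite.  Label switching is
resolved by relabeling classes in descending order of model-implied baseline
mean.  Time is rescaled internally (weeks/10) to condition the quadratic
design; all reported quantities are back-transformed to per-week units.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import logsumexp
from scipy.stats import chi2 as _chi2
from sklearn.cluster import KMeans

from .data import QoLPanel, ValidationError
from .design import build_covariate_design

_LOG2PI = float(np.log(2.0 * np.pi))

SIGMA2_FLOOR = 1e-4
PSI_EIG_FLOOR = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when no EM start converges; carries the per-start traces."""

    def __init__(self, message: str, traces=None):
        super().__init__(message)
        self.traces = traces or []


@dataclass(frozen=True)
class GrowthMixtureSpec:
    """Model definition: class count, polynomial order, conditioning, covariance."""

    n_classes: int
    polynomial_order: int = 2
    growth_covariates: tuple[str, ...] = ()
    class_covariates: tuple[str, ...] = ()
    covariance_mode: str = "shared"
    time_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValidationError("n_classes must be >= 1")
        if self.polynomial_order not in (1, 2):
            raise ValidationError("polynomial_order must be 1 or 2")
        if self.covariance_mode not in ("shared", "class"):
            raise ValidationError("covariance_mode must be 'shared' or 'class'")


@dataclass
class _Params:
    """Internal parameters on the rescaled time axis."""

    log_pi: np.ndarray  # (K,)
    beta: np.ndarray  # (K, p)
    gamma: np.ndarray  # (q,)
    psi: np.ndarray  # (2,2) shared or (K,2,2)
    sigma2: np.ndarray  # scalar array () shared or (K,)
    alpha: np.ndarray | None = None  # (K, 1+qc) class-logit coefs, class 0 ref

    def psi_k(self, k: int) -> np.ndarray:
        return self.psi if self.psi.ndim == 2 else self.psi[k]

    def sigma2_k(self, k: int) -> float:
        return float(self.sigma2) if self.sigma2.ndim == 0 else float(self.sigma2[k])


@dataclass
class GMMFit:
    """A fitted growth mixture model, reported in per-week units."""

    spec: GrowthMixtureSpec
    subject_ids: list[str]
    visit_weeks: np.ndarray
    class_weights: np.ndarray  # marginal class probabilities (mean prior)
    growth_means: np.ndarray  # (K, 3): baseline, slope/week, quad/week^2
    covariate_coefs: pd.Series
    re_cov: np.ndarray  # (2,2) or (K,2,2), per-week units
    resid_var: float | np.ndarray
    loglik: float
    n_params: int
    bic: float
    entropy: float | None
    posterior: np.ndarray  # (n, K)
    modal_class: np.ndarray  # (n,) in 0..K-1
    class_proportions: np.ndarray  # modal-assignment fractions
    growth_factors: np.ndarray  # (n, 3) EB baseline, slope/week, quad/week^2
    converged: bool
    em_trace: np.ndarray
    class_logit: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    _params: _Params | None = field(default=None, repr=False)
    _panel_meta: dict = field(default_factory=dict, repr=False)

    def assignments_frame(self) -> pd.DataFrame:
        """Per-subject classes, posteriors, and EB growth factors."""
        k = self.posterior.shape[1]
        df = pd.DataFrame({"subject_id": self.subject_ids, "modal_class": self.modal_class + 1})
        for j in range(k):
            df[f"p_class{j+1}"] = self.posterior[:, j]
        df["baseline"] = self.growth_factors[:, 0]
        df["slope"] = self.growth_factors[:, 1]
        df["quadratic"] = self.growth_factors[:, 2]
        return df


# ---------------------------------------------------------------------------
# likelihood machinery


def _basis(weeks: np.ndarray, order: int, scale: float) -> np.ndarray:
    s = np.asarray(weeks, dtype=float) / scale
    cols = [np.ones_like(s), s] + ([s**2] if order == 2 else [])
    return np.column_stack(cols)


def _pattern_groups(observed: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group subject indices by their observation mask."""
    keys = [tuple(row) for row in observed]
    seen: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        seen.setdefault(key, []).append(i)
    return [(np.asarray(key, bool), np.asarray(idx)) for key, idx in seen.items()]


def _chol_factor(V: np.ndarray) -> tuple[np.ndarray, float]:
    L = sla.cholesky(V, lower=True)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return L, logdet


class _Workspace:
    """Pre-grouped panel data on the internal time scale."""

    def __init__(self, panel: QoLPanel, spec: GrowthMixtureSpec):
        self.spec = spec
        self.Y = panel.scores
        self.obs = panel.observed
        if not self.obs.any(axis=1).all():
            raise ValidationError("every subject needs at least one observed visit")
        self.Lam = _basis(panel.visit_weeks, spec.polynomial_order, spec.time_scale)
        self.Z = self.Lam[:, :2]
        self.X, self.xnames, _ = build_covariate_design(panel.covariates, spec.growth_covariates)
        if spec.class_covariates:
            Xc, self.cnames, _ = build_covariate_design(panel.covariates, spec.class_covariates)
            self.Xc = np.column_stack([np.ones(len(Xc)), Xc])
        else:
            self.Xc, self.cnames = None, []
        self.groups = _pattern_groups(self.obs)
        self.n, self.m = self.Y.shape
        self.p = self.Lam.shape[1]
        self.q = self.X.shape[1]
        self.n_obs_total = int(self.obs.sum())


def _log_prior(params: _Params, ws: _Workspace) -> np.ndarray:
    """(n, K) log class-membership probabilities."""
    if params.alpha is not None:
        logits = ws.Xc @ params.alpha.T
        return logits - logsumexp(logits, axis=1, keepdims=True)
    return np.broadcast_to(params.log_pi, (ws.n, params.log_pi.size))


def _e_step(params: _Params, ws: _Workspace):
    """Posterior class probabilities, subject logliks, and RE moments.

    Returns (loglik, post, moments) where moments[(g, k)] holds the
    per-pattern conditional random-effect means/covariance needed by the
    M-step.
    """
    K = params.beta.shape[0]
    logjoint = np.empty((ws.n, K))
    log_prior = _log_prior(params, ws)
    c = ws.X @ params.gamma if ws.q else np.zeros(ws.n)
    moments = {}
    for gi, (mask, idx) in enumerate(ws.groups):
        d = int(mask.sum())
        Zg = ws.Z[mask]
        Lg = ws.Lam[mask]
        Yg = ws.Y[np.ix_(idx, np.flatnonzero(mask))]
        for k in range(K):
            psi = params.psi_k(k)
            s2 = params.sigma2_k(k)
            V = Zg @ psi @ Zg.T + s2 * np.eye(d)
            try:
                L, logdet = _chol_factor(V)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
                raise ValidationError(
                    f"observed-visit covariance not positive definite (pattern {gi})"
                ) from exc
            mean = Lg @ params.beta[k]
            R = Yg - c[idx, None] - mean[None, :]
            W = sla.cho_solve((L, True), R.T)  # V^{-1} R'
            quad = np.einsum("ji,ji->i", R.T, W)
            logjoint[idx, k] = -0.5 * (d * _LOG2PI + logdet + quad)
            G = psi @ Zg.T  # (2, d)
            GVinv = sla.cho_solve((L, True), G.T).T  # Psi Z' V^{-1}
            bhat = R @ GVinv.T  # (n_g, 2)
            cvar = psi - GVinv @ Zg @ psi
            moments[(gi, k)] = (bhat, cvar)
    logjoint = logjoint + log_prior
    ll_i = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - ll_i[:, None])
    return float(ll_i.sum()), post, moments


def _fit_class_logit(Xc: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Weighted multinomial-logit M-step for covariate-dependent membership."""
    from sklearn.linear_model import LogisticRegression

    n, K = post.shape
    Xrep = np.repeat(Xc[:, 1:], K, axis=0)
    yrep = np.tile(np.arange(K), n)
    wrep = post.reshape(-1)
    keep = wrep > 1e-12
    lr = LogisticRegression(penalty=None, max_iter=500, tol=1e-8)
    lr.fit(Xrep[keep], yrep[keep], sample_weight=wrep[keep])
    raw = np.column_stack([lr.intercept_, lr.coef_])
    if raw.shape[0] == K:
        alpha = raw
    elif K == 2 and raw.shape[0] == 1:  # sklearn collapses the binary case
        alpha = np.vstack([np.zeros_like(raw[0]), raw[0]])
    else:  # pragma: no cover
        raise RuntimeError("logit M-step returned unexpected shape")
    return alpha - alpha[0]


def _m_step(params: _Params, ws: _Workspace, post: np.ndarray, moments) -> _Params:
    K, p, q = params.beta.shape[0], ws.p, ws.q
    nak = post.sum(axis=0)  # soft class counts

    # class weights / logit
    if params.alpha is not None:
        alpha = _fit_class_logit(ws.Xc, post)
        log_pi = np.log(np.clip(nak / ws.n, 1e-300, None))
    else:
        alpha = None
        log_pi = np.log(np.clip(nak / ws.n, 1e-300, None))

    # fixed effects: weighted OLS of (y - Z bhat) on class-blocked basis + covariates
    dim = K * p + q
    A = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    for gi, (mask, idx) in enumerate(ws.groups):
        Lg = ws.Lam[mask]
        Zg = ws.Z[mask]
        d = Lg.shape[0]
        Yg = ws.Y[np.ix_(idx, np.flatnonzero(mask))]
        LtL = Lg.T @ Lg
        Lt1 = Lg.sum(axis=0)
        Xg = ws.X[idx] if q else np.empty((len(idx), 0))
        if q:
            A[K * p :, K * p :] += d * (Xg.T @ Xg)
        for k in range(K):
            w = post[idx, k]
            bhat, _ = moments[(gi, k)]
            target = Yg - bhat @ Zg.T  # (n_g, d)
            sl = slice(k * p, (k + 1) * p)
            A[sl, sl] += w.sum() * LtL
            rhs[sl] += Lg.T @ (w[:, None] * target).sum(axis=0)
            if q:
                wx = (w[:, None] * Xg).sum(axis=0)
                A[sl, K * p :] += np.outer(Lt1, wx)
                A[K * p :, sl] += np.outer(wx, Lt1)
                rhs[K * p :] += Xg.T @ (w * target.sum(axis=1))
    # tiny ridge keeps the solve stable when a class weight collapses
    ridge = 1e-10 * max(np.trace(A) / dim, 1.0)
    A[np.diag_indices_from(A)] += ridge
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", sla.LinAlgWarning)
            theta = sla.solve(A, rhs, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular fixed-effect design in M-step") from exc
    beta = theta[: K * p].reshape(K, p)
    gamma = theta[K * p :]

    # variance components from conditional RE moments
    shared = params.psi.ndim == 2
    psi_acc = np.zeros((K, 2, 2))
    sse = np.zeros(K)
    dof = np.zeros(K)
    c = ws.X @ gamma if q else np.zeros(ws.n)
    for gi, (mask, idx) in enumerate(ws.groups):
        Lg = ws.Lam[mask]
        Zg = ws.Z[mask]
        Yg = ws.Y[np.ix_(idx, np.flatnonzero(mask))]
        d = Lg.shape[0]
        for k in range(K):
            w = post[idx, k]
            bhat, cvar = moments[(gi, k)]
            psi_acc[k] += (w[:, None, None] * np.einsum("ij,il->ijl", bhat, bhat)).sum(
                axis=0
            ) + w.sum() * cvar
            resid = Yg - c[idx, None] - (Lg @ beta[k])[None, :] - bhat @ Zg.T
            tr = float(np.trace(Zg @ cvar @ Zg.T))
            sse[k] += float((w * np.einsum("ij,ij->i", resid, resid)).sum()) + w.sum() * tr
            dof[k] += w.sum() * d
    if shared:
        psi = _floor_psd(psi_acc.sum(axis=0) / ws.n)
        sigma2 = np.asarray(max(sse.sum() / dof.sum(), SIGMA2_FLOOR))
    else:
        psi = np.stack([_floor_psd(psi_acc[k] / max(nak[k], 1e-12)) for k in range(K)])
        sigma2 = np.maximum(sse / np.maximum(dof, 1e-12), SIGMA2_FLOOR)
    return _Params(log_pi=log_pi, beta=beta, gamma=gamma, psi=psi, sigma2=sigma2, alpha=alpha)


def _floor_psd(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= PSI_EIG_FLOOR:
        return S
    vals = np.clip(vals, PSI_EIG_FLOOR, None)
    return (vecs * vals) @ vecs.T


# ---------------------------------------------------------------------------
# initialization


def _pooled_covariate_coefs(ws: _Workspace) -> np.ndarray:
    """Pooled-OLS covariate effects used to de-confound the init clustering."""
    if ws.q == 0:
        return np.zeros(0)
    rows_L, rows_X, ys = [], [], []
    for mask, idx in ws.groups:
        Lg = ws.Lam[mask]
        for i in idx:
            rows_L.append(Lg)
            rows_X.append(np.repeat(ws.X[i][None, :], Lg.shape[0], axis=0))
            ys.append(ws.Y[i, mask])
    D = np.column_stack([np.vstack(rows_L), np.vstack(rows_X)])
    y = np.concatenate(ys)
    theta = np.linalg.lstsq(D, y, rcond=None)[0]
    return theta[ws.p :]


def _subject_ols_coefs(ws: _Workspace, gamma0: np.ndarray) -> np.ndarray:
    shift = ws.X @ gamma0 if ws.q else np.zeros(ws.n)
    coefs = np.zeros((ws.n, ws.p))
    for i in range(ws.n):
        mask = ws.obs[i]
        Lg = ws.Lam[mask]
        y = ws.Y[i, mask] - shift[i]
        coefs[i] = np.linalg.lstsq(Lg, y, rcond=None)[0]
    return coefs


def _initial_params(ws: _Workspace, K: int, rng: np.random.Generator, perturb: bool) -> _Params:
    gamma0 = _pooled_covariate_coefs(ws)
    coefs = _subject_ols_coefs(ws, gamma0)
    # cluster on intercept/slope only: per-subject quadratic estimates are
    # noisy (many subjects have few visits) and would swamp the k-means
    feats = coefs[:, :2]
    scale = feats.std(axis=0)
    scale[scale < 1e-8] = 1.0
    km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(feats / scale)
    if perturb and rng.random() < 0.3:
        # occasionally shuffle a fifth of the labels for basin diversity
        flip = rng.random(ws.n) < 0.2
        labels = np.where(flip, rng.integers(K, size=ws.n), labels)
    beta = np.zeros((K, ws.p))
    resid_var = []
    within = []
    for k in range(K):
        sel = labels == k
        if sel.sum() == 0:
            beta[k] = coefs[rng.integers(ws.n)]
            continue
        beta[k] = coefs[sel].mean(axis=0)
        if sel.sum() > 2:
            within.append(np.cov(coefs[sel][:, :2].T))
    for i in range(ws.n):
        mask = ws.obs[i]
        resid = ws.Y[i, mask] - ws.Lam[mask] @ coefs[i]
        resid_var.extend(resid**2)
    if perturb:
        spread = np.maximum(beta.std(axis=0), 1e-2)
        beta = beta + rng.normal(0.0, 1.0, beta.shape) * (0.5 * spread)[None, :]
    psi0 = _floor_psd(np.mean(within, axis=0) if within else np.diag([25.0, 1.0]))
    sigma2 = np.asarray(max(float(np.mean(resid_var)) if resid_var else 25.0, 1.0))
    pi = np.bincount(labels, minlength=K).astype(float)
    pi = np.clip(pi / pi.sum(), 0.05, None)
    pi /= pi.sum()
    alpha = np.zeros((K, ws.Xc.shape[1])) if ws.Xc is not None else None
    if alpha is not None:
        alpha[:, 0] = np.log(pi) - np.log(pi[0])
    return _Params(
        log_pi=np.log(pi),
        beta=beta,
        gamma=gamma0,
        psi=psi0,
        sigma2=sigma2,
        alpha=alpha,
    )


def _promote_covmode(params: _Params, spec: GrowthMixtureSpec, K: int) -> _Params:
    if spec.covariance_mode == "class" and params.psi.ndim == 2:
        return replace(
            params,
            psi=np.stack([params.psi.copy() for _ in range(K)]),
            sigma2=np.full(K, float(params.sigma2)),
        )
    return params


# ---------------------------------------------------------------------------
# public operations


def n_parameters(spec: GrowthMixtureSpec, n_covariates: int, n_class_covariates: int = 0) -> int:
    """Free-parameter count used in the BIC.

    class weights (K-1, or (K-1)(1+qc) with a covariate logit) + K growth
    means per basis column + covariate shifts + random-effect covariance
    (3 entries, per class if class-specific) + residual variance.
    """
    K = spec.n_classes
    p = spec.polynomial_order + 1
    if spec.class_covariates:
        w = (K - 1) * (1 + n_class_covariates)
    else:
        w = K - 1
    cov = 4 if spec.covariance_mode == "shared" else 4 * K
    return w + K * p + n_covariates + cov


def fit_gmm(
    panel: QoLPanel,
    spec: GrowthMixtureSpec,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    short_iter: int = 40,
) -> GMMFit:
    """Fit the growth mixture model by multi-start EM.

    Each start runs a short EM burst; the best is continued to convergence
    (relative log-likelihood change below ``tol``).  Classes are relabeled in
    descending order of model-implied baseline mean so labels are stable
    across seeds on well-separated data.
    """
    if spec.n_classes > max(panel.n_subjects // 10, 1):
        raise ValidationError(
            f"K={spec.n_classes} too large for {panel.n_subjects} subjects (need K <= n/10)"
        )
    ws = _Workspace(panel, spec)
    rng = np.random.default_rng(seed)
    K = spec.n_classes

    best: tuple[float, _Params] | None = None
    traces = []
    for s in range(max(n_starts, 1)):
        params = _promote_covmode(_initial_params(ws, K, rng, perturb=s > 0), spec, K)
        try:
            params, trace, _ = _run_em(params, ws, short_iter if n_starts > 1 else max_iter, tol)
        except (ValidationError, np.linalg.LinAlgError):
            continue
        traces.append(trace)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params)
    if best is None:
        raise ConvergenceError("all EM starts failed", traces)

    params, trace, converged = _run_em(best[1], ws, max_iter, tol)
    loglik, post, moments = _e_step(params, ws)
    trace = np.append(trace, loglik)

    params, post, moments = _relabel(params, ws, post, moments)
    return _assemble_fit(panel, spec, ws, params, post, moments, loglik, trace, converged)


def _run_em(params: _Params, ws: _Workspace, max_iter: int, tol: float):
    ll_prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        ll, post, moments = _e_step(params, ws)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (1.0 + abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
        params = _m_step(params, ws, post, moments)
    return params, np.asarray(trace), converged


def _relabel(params: _Params, ws: _Workspace, post: np.ndarray, moments):
    order = np.argsort(-params.beta[:, 0], kind="stable")
    if np.array_equal(order, np.arange(len(order))):
        return params, post, moments
    remap = {int(old): new for new, old in enumerate(order)}
    new_moments = {
        (gi, remap[k]): v for (gi, k), v in moments.items()
    }
    alpha = params.alpha
    if alpha is not None:
        alpha = alpha[order]
        alpha = alpha - alpha[0]
    params = _Params(
        log_pi=params.log_pi[order],
        beta=params.beta[order],
        gamma=params.gamma,
        psi=params.psi if params.psi.ndim == 2 else params.psi[order],
        sigma2=params.sigma2 if params.sigma2.ndim == 0 else params.sigma2[order],
        alpha=alpha,
    )
    return params, post[:, order], new_moments


def _assemble_fit(panel, spec, ws, params, post, moments, loglik, trace, converged) -> GMMFit:
    K = spec.n_classes
    c = spec.time_scale
    p = ws.p
    means = np.zeros((K, 3))
    means[:, 0] = params.beta[:, 0]
    means[:, 1] = params.beta[:, 1] / c
    if p == 3:
        means[:, 2] = params.beta[:, 2] / c**2
    scale = np.array([[1.0, 1.0 / c], [1.0 / c, 1.0 / c**2]])
    re_cov = params.psi * scale if params.psi.ndim == 2 else params.psi * scale[None, :, :]
    resid_var = float(params.sigma2) if params.sigma2.ndim == 0 else np.asarray(params.sigma2)

    modal = post.argmax(axis=1)
    props = np.bincount(modal, minlength=K) / ws.n
    npar = n_parameters(spec, ws.q, len(ws.cnames))
    warnings_ = []
    if (np.exp(params.log_pi) < 1.0 / ws.n).any():
        warnings_.append("degenerate class: prior weight below 1/n")
    growth = _eb_from_moments(params, ws, post, moments, c)
    ent = entropy(post) if K >= 2 else None
    fit = GMMFit(
        spec=spec,
        subject_ids=list(panel.subject_ids),
        visit_weeks=panel.visit_weeks.copy(),
        class_weights=np.exp(params.log_pi),
        growth_means=means,
        covariate_coefs=pd.Series(params.gamma, index=ws.xnames, dtype=float),
        re_cov=re_cov,
        resid_var=resid_var,
        loglik=float(loglik),
        n_params=npar,
        bic=bic(loglik, npar, ws.n),
        entropy=ent,
        posterior=post,
        modal_class=modal,
        class_proportions=props,
        growth_factors=growth,
        converged=converged,
        em_trace=trace,
        class_logit=None if params.alpha is None else params.alpha.copy(),
        warnings=warnings_,
        _params=params,
        _panel_meta={"n_obs": ws.n_obs_total},
    )
    return fit


def _eb_from_moments(params: _Params, ws: _Workspace, post, moments, c) -> np.ndarray:
    """Posterior-weighted empirical-Bayes growth factors, per-week units."""
    K = params.beta.shape[0]
    cshift = ws.X @ params.gamma if ws.q else np.zeros(ws.n)
    out = np.zeros((ws.n, 3))
    for gi, (mask, idx) in enumerate(ws.groups):
        for k in range(K):
            bhat, _ = moments[(gi, k)]
            w = post[idx, k][:, None]
            eta = params.beta[k, :2][None, :] + bhat  # internal units
            out[idx, 0] += (w * (eta[:, :1] + cshift[idx, None]))[:, 0]
            out[idx, 1] += (w * eta[:, 1:2])[:, 0] / c
            if ws.p == 3:
                out[idx, 2] += post[idx, k] * params.beta[k, 2] / c**2
    return out


def eb_growth_factors(fit: GMMFit, panel: QoLPanel) -> pd.DataFrame:
    """Per-subject (baseline, slope/week, quadratic/week^2) EB estimates.

    Baseline and slope are posterior-weighted conditional means of the
    latent growth factors given the subject's observed visits; the quadratic
    is the posterior-weighted class fixed effect.
    """
    if fit._params is None:
        raise ValidationError("fit does not carry internal parameters")
    missing = set(panel.subject_ids) - set(fit.subject_ids)
    if missing:
        raise ValidationError(f"subjects absent from fit: {sorted(missing)[:5]}")
    ws = _Workspace(panel, fit.spec)
    _, post, moments = _e_step(fit._params, ws)
    order = np.argsort(-fit._params.beta[:, 0], kind="stable")
    assert np.array_equal(order, np.arange(len(order)))
    growth = _eb_from_moments(fit._params, ws, post, moments, fit.spec.time_scale)
    return pd.DataFrame(
        growth, columns=["baseline", "slope", "quadratic"], index=panel.subject_ids
    )


def subject_class_loglik(
    fit: GMMFit,
    observed_weeks: np.ndarray,
    y_observed: np.ndarray,
    covariate_row: pd.Series | None = None,
) -> np.ndarray:
    """Per-class log-density of one subject's observed visits (FIML).

    The density for class ``k`` is multivariate normal with mean
    ``Lambda beta_k + gamma'x`` and covariance ``Z Psi Z' + sigma^2 I``
    restricted to the observed weeks.  The class prior is not included.
    """
    params = fit._params
    if params is None:
        raise ValidationError("fit does not carry internal parameters")
    spec = fit.spec
    weeks = np.asarray(observed_weeks, dtype=float)
    y = np.asarray(y_observed, dtype=float)
    if weeks.size == 0 or weeks.size != y.size:
        raise ValidationError("need matching, non-empty observed weeks and values")
    Lam = _basis(weeks, spec.polynomial_order, spec.time_scale)
    Z = Lam[:, :2]
    if spec.growth_covariates:
        if covariate_row is None:
            raise ValidationError("covariate_row required for a conditional model")
        X, _, _ = build_covariate_design(covariate_row.to_frame().T, spec.growth_covariates)
        shift = float(X[0] @ params.gamma)
    else:
        shift = 0.0
    K = params.beta.shape[0]
    out = np.zeros(K)
    d = weeks.size
    for k in range(K):
        V = Z @ params.psi_k(k) @ Z.T + params.sigma2_k(k) * np.eye(d)
        try:
            L, logdet = _chol_factor(V)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("observed-visit covariance not positive definite") from exc
        r = y - Lam @ params.beta[k] - shift
        w = sla.cho_solve((L, True), r)
        out[k] = -0.5 * (d * _LOG2PI + logdet + float(r @ w))
    return out


def entropy(posterior: np.ndarray) -> float:
    """Relative entropy of a posterior matrix: 1 = crisp, 0 = uninformative.

    ``E = 1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K)``; undefined for K=1.
    """
    P = np.asarray(posterior, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValidationError("entropy requires a posterior with K >= 2 columns")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("posterior rows must sum to 1")
    n, K = P.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """``-2 loglik + n_params ln(n_subjects)``; the sample size is subjects."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    return -2.0 * float(loglik) + n_params * float(np.log(n_subjects))


def lrt_same_k(fit_restricted: GMMFit, fit_full: GMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test between nested fits with the same K."""
    if fit_restricted.spec.n_classes != fit_full.spec.n_classes:
        raise ValidationError("likelihood-ratio comparison requires the same class count")
    df = fit_full.n_params - fit_restricted.n_params
    if df <= 0:
        raise ValidationError("full model must have more parameters than the restricted one")
    stat = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    if stat < -1e-6:
        raise ValidationError(
            f"negative LR statistic ({stat:.3g}): models not nested or not converged"
        )
    stat = max(stat, 0.0)
    return stat, df, float(_chi2.sf(stat, df))


@dataclass
class ModelSelectionReport:
    """Per-K fits plus the constrained BIC choice."""

    fits: dict[int, GMMFit]
    failures: dict[int, str]
    chosen_k: int
    constraint_violated: bool
    table: pd.DataFrame

    @property
    def chosen_fit(self) -> GMMFit:
        return self.fits[self.chosen_k]


def select_num_classes(
    panel: QoLPanel,
    spec_template: GrowthMixtureSpec,
    k_range=(1, 2, 3, 4, 5),
    min_prop: float = 0.10,
    entropy_floor: float = 0.7,
    enforce_entropy: bool = True,
    **fit_kwargs,
) -> ModelSelectionReport:
    """Fit each candidate K and choose the BIC minimizer under the class rules.

    A candidate is admissible when every modal class holds at least
    ``min_prop`` of subjects and (for K >= 2, if ``enforce_entropy``) the
    relative entropy reaches ``entropy_floor``.  If no candidate is
    admissible the unconstrained BIC minimizer is returned with
    ``constraint_violated`` set.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("k_range must be non-empty")
    fits: dict[int, GMMFit] = {}
    failures: dict[int, str] = {}
    for k in ks:
        try:
            fits[k] = fit_gmm(panel, replace(spec_template, n_classes=k), **fit_kwargs)
        except (ValidationError, ConvergenceError) as exc:
            failures[k] = str(exc)
    if not fits:
        raise ConvergenceError(f"no candidate K converged: {failures}")

    rows = []
    admissible = []
    for k, fit in fits.items():
        ok_prop = bool(fit.class_proportions.min() >= min_prop)
        ok_ent = True if (k == 1 or not enforce_entropy) else bool(
            (fit.entropy or 0.0) >= entropy_floor
        )
        if ok_prop and ok_ent:
            admissible.append(k)
        rows.append(
            {
                "K": k,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "bic": fit.bic,
                "entropy": fit.entropy,
                "min_proportion": fit.class_proportions.min(),
                "admissible": ok_prop and ok_ent,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("K").sort_index()
    pool = admissible if admissible else list(fits)
    chosen = min(pool, key=lambda k: fits[k].bic)
    return ModelSelectionReport(
        fits=fits,
        failures=failures,
        chosen_k=chosen,
        constraint_violated=not admissible,
        table=table,
    )
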