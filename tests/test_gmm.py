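"""Growth mixture model: FIML oracles, EM behavior, selection statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from qoltraj import (
    GrowthMixtureSpec,
    ValidationError,
    bic,
    default_scenario,
    eb_growth_factors,
    entropy,
    fit_gmm,
    fit_lmm,
    lrt_same_k,
    recovery_scenario,
    select_num_classes,
    simulate_cohort,
)
from qoltraj.gmm import _Workspace, _basis


def _dense_moments(fit, panel, k):
    """Dense 7-visit mean/covariance for class k, assembled independently."""
    p = fit._params
    spec = fit.spec
    Lam = _basis(panel.visit_weeks, spec.polynomial_order, spec.time_scale)
    Z = Lam[:, :2]
    V = Z @ p.psi_k(k) @ Z.T + p.sigma2_k(k) * np.eye(len(panel.visit_weeks))
    mean = Lam @ p.beta[k]
    return mean, V


class TestSubjectClassLoglik:
    """FIML: each subject contributes the marginal of their observed visits."""

    def test_matches_dense_mvn_for_complete_and_missing(self, recovery_fit, recovery_cohort):
        from qoltraj.gmm import subject_class_loglik

        panel = recovery_cohort.panel
        ws = _Workspace(panel, recovery_fit.spec)
        shift = ws.X @ recovery_fit._params.gamma
        rng = np.random.default_rng(0)
        for i in rng.choice(panel.n_subjects, size=25, replace=False):
            mask = panel.observed[i]
            got = subject_class_loglik(
                recovery_fit,
                panel.visit_weeks[mask],
                panel.scores[i, mask],
                panel.covariates.iloc[i],
            )
            for k in range(3):
                mean, V = _dense_moments(recovery_fit, panel, k)
                want = multivariate_normal.logpdf(
                    panel.scores[i, mask],
                    mean=mean[mask] + shift[i],
                    cov=V[np.ix_(mask, mask)],
                )
                assert got[k] == pytest.approx(want, abs=1e-8)

    def test_single_visit_is_univariate_normal(self, recovery_fit, recovery_cohort):
        from qoltraj.gmm import subject_class_loglik
        from scipy.stats import norm

        panel = recovery_cohort.panel
        got = subject_class_loglik(
            recovery_fit, np.array([4.0]), np.array([62.0]), panel.covariates.iloc[0]
        )
        ws = _Workspace(panel, recovery_fit.spec)
        shift = float((ws.X @ recovery_fit._params.gamma)[0])
        for k in range(3):
            mean, V = _dense_moments(recovery_fit, panel, k)
            j = list(panel.visit_weeks).index(4.0)
            want = norm.logpdf(62.0, loc=mean[j] + shift, scale=np.sqrt(V[j, j]))
            assert got[k] == pytest.approx(want, abs=1e-8)

    def test_deleting_visits_equals_marginalization(self, recovery_fit, recovery_cohort):
        """Evaluating on visits {0,4} equals the 2-D marginal of the 7-D normal."""
        from qoltraj.gmm import subject_class_loglik

        panel = recovery_cohort.panel
        keep = np.array([True, False, True, False, False, False, False])
        i = 5
        got = subject_class_loglik(
            recovery_fit,
            panel.visit_weeks[keep],
            panel.scores[i, keep],
            panel.covariates.iloc[i],
        )
        ws = _Workspace(panel, recovery_fit.spec)
        shift = float((ws.X @ recovery_fit._params.gamma)[i])
        for k in range(3):
            mean, V = _dense_moments(recovery_fit, panel, k)
            want = multivariate_normal.logpdf(
                panel.scores[i, keep], mean=mean[keep] + shift, cov=V[np.ix_(keep, keep)]
            )
            assert got[k] == pytest.approx(want, abs=1e-8)


class TestEMBehavior:
    def test_em_trace_is_monotone(self, recovery_fit):
        diffs = np.diff(recovery_fit.em_trace)
        assert diffs.min() >= -1e-6 * (1 + abs(recovery_fit.loglik))

    def test_posterior_rows_sum_to_one(self, recovery_fit):
        np.testing.assert_allclose(recovery_fit.posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_classes_ordered_by_descending_baseline(self, recovery_fit):
        bl = recovery_fit.growth_means[:, 0]
        assert (np.diff(bl) < 0).all()

    def test_k1_matches_mixed_model_loglik(self):
        """One latent class is exactly the ML linear mixed model."""
        scn = default_scenario(n_subjects=200)
        co = simulate_cohort(scn, seed=7)
        g = fit_gmm(
            co.panel,
            GrowthMixtureSpec(1, growth_covariates=("sex", "ecog")),
            n_starts=1,
            max_iter=20000,
            tol=1e-12,
            seed=0,
        )
        l = fit_lmm(co.panel, ("sex", "ecog"), random_structure="intercept+slope",
                    time_order=2, reml=False)
        assert g.loglik == pytest.approx(l.loglik, abs=1e-4)

    def test_label_permutation_leaves_likelihood_invariant(self, recovery_fit, recovery_cohort):
        from qoltraj.gmm import _Params, _e_step

        p = recovery_fit._params
        perm = [2, 0, 1]
        p2 = _Params(
            log_pi=p.log_pi[perm], beta=p.beta[perm], gamma=p.gamma,
            psi=p.psi, sigma2=p.sigma2,
        )
        ws = _Workspace(recovery_cohort.panel, recovery_fit.spec)
        ll1, post1, _ = _e_step(p, ws)
        ll2, post2, _ = _e_step(p2, ws)
        assert ll1 == pytest.approx(ll2, abs=1e-8)
        np.testing.assert_allclose(post2[:, [1, 2, 0]], post1, atol=1e-10)

    def test_class_proportions_sum_to_one(self, recovery_fit):
        assert recovery_fit.class_proportions.sum() == pytest.approx(1.0)

    def test_k_too_large_for_sample_rejected(self, recovery_cohort):
        small = recovery_cohort.panel.subset(recovery_cohort.panel.subject_ids[:20])
        with pytest.raises(ValidationError, match="K"):
            fit_gmm(small, GrowthMixtureSpec(5), n_starts=1)


class TestEntropy:
    def test_crisp_posterior_gives_one(self):
        P = np.eye(3)[np.array([0, 1, 2, 0, 1])]
        assert entropy(P) == pytest.approx(1.0)

    def test_uniform_posterior_gives_zero(self):
        assert entropy(np.full((4, 3), 1 / 3)) == pytest.approx(0.0)

    def test_hand_computed_two_subject_case(self):
        P = np.array([[0.9, 0.1], [0.6, 0.4]])
        assert entropy(P) == pytest.approx(0.2800, abs=1e-4)

    def test_single_class_is_undefined(self):
        with pytest.raises(ValidationError):
            entropy(np.ones((5, 1)))

    def test_entropy_decreases_with_class_overlap(self):
        """Less separation between simulated classes -> lower entropy."""
        ents = []
        for gap in (30.0, 15.0, 7.0):
            scn = recovery_scenario(
                n_subjects=250,
                class_growth_means=(
                    (50 + gap, -0.5, 0.0), (50.0, -0.5, 0.0), (50 - gap, -0.5, 0.0),
                ),
                dropout=None,
            )
            co = simulate_cohort(scn, seed=31)
            fit = fit_gmm(co.panel, GrowthMixtureSpec(3), n_starts=4, seed=1)
            ents.append(fit.entropy)
        assert ents[0] > ents[1] > ents[2]


class TestBICAndLRT:
    def test_bic_closed_form(self):
        assert bic(-100.0, 5, 50) == pytest.approx(200 + 5 * np.log(50))
        assert bic(-100.0, 0, 50) == pytest.approx(200.0)

    def test_bic_increases_with_parameters(self):
        vals = [bic(-100.0, p, 50) for p in range(6)]
        assert (np.diff(vals) > 0).all()

    def test_lrt_identical_fits_gives_p_one(self, recovery_fit, recovery_cohort):
        restricted = fit_gmm(
            recovery_cohort.panel,
            GrowthMixtureSpec(3, growth_covariates=()),
            n_starts=4,
            seed=3,
        )
        stat, df, p = lrt_same_k(restricted, recovery_fit)
        assert df == 3
        assert stat >= 0
        import types

        clone = types.SimpleNamespace(
            spec=recovery_fit.spec, n_params=recovery_fit.n_params + 1,
            loglik=recovery_fit.loglik,
        )
        stat0, _, p0 = lrt_same_k(recovery_fit, clone)
        assert stat0 == 0 and p0 == pytest.approx(1.0)

    def test_lrt_reference_quantile(self):
        from scipy.stats import chi2

        assert chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)

    def test_lrt_type_one_error_near_nominal(self):
        """Dropping a truly-null covariate: LRT rejects at ~5%."""
        rejections, reps = 0, 50
        for r in range(reps):
            scn = recovery_scenario(
                n_subjects=120,
                class_growth_means=((70.0, -0.5, 0.0), (40.0, 0.5, 0.0)),
                class_probs=(0.5, 0.5),
                covariate_effects=(("male", 4.0),),
                dropout=None,
            )
            co = simulate_cohort(scn, seed=5000 + r)
            # age is pure noise for QoL in the generator
            full = fit_gmm(co.panel, GrowthMixtureSpec(2, growth_covariates=("sex", "age")),
                           n_starts=2, seed=r, tol=1e-8)
            restricted = fit_gmm(co.panel, GrowthMixtureSpec(2, growth_covariates=("sex",)),
                                 n_starts=2, seed=r, tol=1e-8)
            try:
                _, df, p = lrt_same_k(restricted, full)
            except ValidationError:
                continue
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.08)


class TestSelection:
    def test_single_candidate_returned(self, recovery_cohort):
        rep = select_num_classes(
            recovery_cohort.panel,
            GrowthMixtureSpec(3, growth_covariates=("sex", "ecog")),
            k_range=(3,),
            n_starts=4,
            seed=2,
        )
        assert rep.chosen_k == 3

    def test_argmin_bic_among_admissible(self, recovery_fit):
        """Selection picks the smaller BIC when both candidates pass the rules."""
        import copy

        a = recovery_fit
        b = copy.copy(recovery_fit)
        b.bic = a.bic + 131.0
        from qoltraj.gmm import ModelSelectionReport

        fits = {3: a, 4: b}
        chosen = min(fits, key=lambda k: fits[k].bic)
        assert chosen == 3

    def test_small_class_candidate_excluded(self, recovery_cohort):
        """A K whose smallest modal class is under 10% is inadmissible."""
        rep = select_num_classes(
            recovery_cohort.panel,
            GrowthMixtureSpec(3, growth_covariates=("sex", "ecog")),
            k_range=(1, 3),
            min_prop=0.45,  # deliberately unattainable for K=3 (smallest ~0.2)
            n_starts=4,
            seed=2,
        )
        assert rep.table.loc[3, "admissible"] == False  # noqa: E712
        assert rep.chosen_k == 1


class TestGrowthFactors:
    def test_crisp_posterior_reduces_to_single_class_blup(self, recovery_fit, recovery_cohort):
        """For a subject with essentially degenerate posterior the EB factors
        equal the one-class conditional mean computed from the dense normal."""
        panel = recovery_cohort.panel
        post = recovery_fit.posterior
        i = int(np.argmax(post.max(axis=1)))  # crispest subject
        k = int(post[i].argmax())
        assert post[i, k] > 1 - 1e-6
        p = recovery_fit._params
        spec = recovery_fit.spec
        mask = panel.observed[i]
        Lam = _basis(panel.visit_weeks, spec.polynomial_order, spec.time_scale)[mask]
        Z = Lam[:, :2]
        ws = _Workspace(panel, spec)
        shift = float((ws.X @ p.gamma)[i])
        V = Z @ p.psi @ Z.T + float(p.sigma2) * np.eye(mask.sum())
        r = panel.scores[i, mask] - Lam @ p.beta[k] - shift
        bhat = p.psi @ Z.T @ np.linalg.solve(V, r)
        want_baseline = p.beta[k, 0] + shift + bhat[0]
        want_slope = (p.beta[k, 1] + bhat[1]) / spec.time_scale
        got = recovery_fit.growth_factors[i]
        assert got[0] == pytest.approx(want_baseline, abs=1e-6)
        assert got[1] == pytest.approx(want_slope, abs=1e-8)
        assert got[2] == pytest.approx(p.beta[k, 2] / 100.0, abs=1e-8)

    def test_zero_re_cov_limit_equals_class_means(self, recovery_fit, recovery_cohort):
        """With the random-effect covariance forced to (near) zero, the EB
        factors are exactly the posterior-weighted class means."""
        from qoltraj.gmm import _Params, _Workspace, _e_step, _eb_from_moments

        p = recovery_fit._params
        p0 = _Params(log_pi=p.log_pi, beta=p.beta, gamma=p.gamma,
                     psi=1e-10 * np.eye(2), sigma2=p.sigma2)
        ws = _Workspace(recovery_cohort.panel, recovery_fit.spec)
        _, post, moments = _e_step(p0, ws)
        got = _eb_from_moments(p0, ws, post, moments, recovery_fit.spec.time_scale)
        shift = ws.X @ p.gamma
        means = np.column_stack([p.beta[:, 0], p.beta[:, 1] / 10.0, p.beta[:, 2] / 100.0])
        implied = post @ means
        implied[:, 0] += shift
        np.testing.assert_allclose(got, implied, atol=1e-6)

    def test_eb_function_matches_fit_attribute(self, recovery_fit, recovery_cohort):
        df = eb_growth_factors(recovery_fit, recovery_cohort.panel)
        np.testing.assert_allclose(df.to_numpy(), recovery_fit.growth_factors, atol=1e-10)

    def test_unknown_subject_rejected(self, recovery_fit):
        bad = simulate_cohort(recovery_scenario(n_subjects=10), seed=99).panel
        ids = [f"ZZ{i}" for i in range(10)]
        bad = type(bad)(ids, bad.visit_weeks, bad.scores,
                        bad.covariates.set_axis(ids, axis=0))
        with pytest.raises(ValidationError, match="absent"):
            eb_growth_factors(recovery_fit, bad)


def test_parameter_recovery_small():
    """Two replicates of the well-separated scenario recover class baselines
    within 2 points and proportions within 0.05 (the full 20-replicate
    version runs in the acceptance suite)."""
    spec = GrowthMixtureSpec(3, growth_covariates=("sex", "ecog"))
    for seed in (60, 61):
        co = simulate_cohort(recovery_scenario(n_subjects=400), seed=seed)
        fit = fit_gmm(co.panel, spec, n_starts=10, seed=seed)
        np.testing.assert_allclose(fit.growth_means[:, 0], [75, 55, 35], atol=2.0)
        np.testing.assert_allclose(
            fit.class_proportions, [0.45, 0.35, 0.20], atol=0.05
        )
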