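"""FIML likelihood, reference models, fit indices and standard errors."""

import numpy as np
import pytest
from scipy import stats

from metatraj.estimation import (
    FitOptions,
    JointMomentModel,
    baseline_fit,
    classify_cfi,
    classify_srmr,
    expected_information,
    fiml_loglik,
    fit,
    fit_indices,
    fit_moment_model,
    prepare_patterns,
    saturated_fit,
    srmr_from_moments,
    standard_errors,
    SaturatedResult,
)
from metatraj.model import (
    build_index_map,
    implied_moments,
    moment_maps,
    n_free_parameters,
    pack_parameters,
)


class TestLoglik:
    def test_single_observation_matches_univariate_normal(self, spec, params):
        """One participant with one observed value contributes exactly the
        univariate normal log-density at the implied mean and variance."""
        imap = build_index_map(spec)
        pos = imap.index("bmi", 0)
        y = 27.3
        w = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 3.0])
        Y = np.full((1, 26), np.nan)
        Y[0, pos] = y
        ms = implied_moments(params, w, spec)
        expected = stats.norm.logpdf(y, ms.mu[pos], np.sqrt(ms.Sigma[pos, pos]))
        got = fiml_loglik(params, (Y, w[None, :]), spec)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_duplicating_participants_doubles_loglik(self, spec, params, mar_cohort):
        Y, W = mar_cohort.to_matrices(spec)
        ll1 = fiml_loglik(params, (Y, W), spec)
        ll2 = fiml_loglik(params, (np.vstack([Y, Y]), np.vstack([W, W])), spec)
        np.testing.assert_allclose(ll2, 2.0 * ll1, rtol=1e-12)

    def test_participant_order_invariance(self, spec, params, mar_cohort):
        Y, W = mar_cohort.to_matrices(spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(Y.shape[0])
        ll = fiml_loglik(params, (Y, W), spec)
        llp = fiml_loglik(params, (Y[perm], W[perm]), spec)
        assert abs(ll - llp) < 1e-9

    def test_all_missing_row_rejected(self, spec, params):
        Y = np.full((2, 26), np.nan)
        Y[0, 0] = 25.0
        with pytest.raises(ValueError, match="at least one observed"):
            fiml_loglik(params, (Y, np.zeros((2, 6))), spec)

    def test_singular_sigma_returns_minus_inf_sentinel(self):
        """A non-PD restricted covariance yields the -inf sentinel (so an
        optimizer can retreat), not an exception."""
        from metatraj.estimation import _pattern_loglik

        Y = np.array([[1.0, 2.0], [0.5, 1.5]])
        pats = prepare_patterns(Y, np.zeros((2, 0)))
        Sigma = np.array([[1.0, 1.0], [1.0, 1.0]])   # rank 1
        ll = _pattern_loglik(np.zeros(2), np.zeros((2, 0)), Sigma, pats)
        assert ll == -np.inf


class TestSaturatedAndBaseline:
    def test_complete_data_saturated_equals_sample_moments(self, spec, params, complete_cohort):
        Y, W = complete_cohort.to_matrices(spec)
        sat = saturated_fit((Y, W), use_covariates=False)
        np.testing.assert_allclose(sat.Pi[:, 0], Y.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(sat.Sigma, np.cov(Y.T, bias=True), atol=1e-8)

    def test_em_matches_direct_fiml_optimizer_on_toy(self):
        """Unrestricted means/covariance on a 3-variable toy with deletions:
        the EM solution coincides with direct quasi-Newton FIML maximization
        of the same unstructured model."""
        rng = np.random.default_rng(3)
        n = 60
        L = np.array([[1.0, 0, 0], [0.4, 0.8, 0], [0.2, 0.3, 0.7]])
        Y = rng.standard_normal((n, 3)) @ L.T + [1.0, -0.5, 2.0]
        Y[rng.random((n, 3)) < 0.15] = np.nan
        Y[np.isnan(Y).all(axis=1), 0] = 0.0
        W = np.zeros((n, 0))

        class Unstructured:
            n_free = 3 + 6

            def moments(self, th):
                M0 = th[:3]
                Lc = np.zeros((3, 3), dtype=th.dtype)
                idx = 3
                for i in range(3):
                    for j in range(i + 1):
                        Lc[i, j] = np.exp(th[idx]) if i == j else th[idx]
                        idx += 1
                return M0, np.zeros((3, 0), dtype=th.dtype), Lc @ Lc.T

        sat = saturated_fit((Y, W), use_covariates=False, tol=1e-12)
        th0 = np.zeros(9)
        th0[:3] = np.nanmean(Y, axis=0)
        pf = fit_moment_model(Unstructured(), Y, W, th0,
                              FitOptions(starts=1, tol=1e-12, max_iter=2000))
        M0, _, Sigma = Unstructured().moments(pf.theta)
        np.testing.assert_allclose(pf.loglik, sat.loglik, atol=1e-6)
        np.testing.assert_allclose(M0, sat.Pi[:, 0], atol=1e-4)
        np.testing.assert_allclose(Sigma, sat.Sigma, atol=1e-3)

    def test_nesting_order_of_logliks(self, spec, params, mar_cohort):
        """saturated >= structured-model >= independence-baseline likelihood."""
        Y, W = mar_cohort.to_matrices(spec)
        sat = saturated_fit((Y, W))
        base = baseline_fit(Y)
        ll = fiml_loglik(params, (Y, W), spec)
        assert sat.loglik >= ll - 1e-6
        assert ll >= base.loglik


class TestFitIndices:
    def test_saturated_self_comparison_is_perfect_fit(self, spec, params, mar_cohort):
        Y, W = mar_cohort.to_matrices(spec)
        sat = saturated_fit((Y, W))
        base = baseline_fit(Y)
        moments = (sat.Pi[:, 0], sat.Pi[:, 1:], sat.Sigma)
        fi = fit_indices(sat.loglik, sat, base, n_free=sat.n_params - 26,
                         model_moments=moments, W=W)
        assert fi.chi2 == 0.0
        assert fi.srmr == 0.0
        assert fi.cfi == 1.0

    def test_srmr_matches_hand_computation_on_toy(self):
        """3 variables, intercept-only: SRMR recomputed element by element
        from its definition."""
        S = np.array([[4.0, 1.2, 0.5], [1.2, 2.25, 0.3], [0.5, 0.3, 1.0]])
        m_sat = np.array([1.0, -0.5, 2.0])
        Pi = m_sat[:, None]
        sat = SaturatedResult(Pi=Pi, Sigma=S, loglik=0.0, n_params=9,
                              n_iter=1, converged=True)
        Sm = np.array([[3.6, 1.0, 0.6], [1.0, 2.5, 0.2], [0.6, 0.2, 0.9]])
        mm = np.array([1.1, -0.4, 1.9])
        sd = np.sqrt(np.diag(S))
        total, cnt = 0.0, 0
        for i in range(3):
            total += ((m_sat[i] - mm[i]) / sd[i]) ** 2
            cnt += 1
            for j in range(i + 1):
                total += ((S[i, j] - Sm[i, j]) / (sd[i] * sd[j])) ** 2
                cnt += 1
        expected = np.sqrt(total / cnt)
        got = srmr_from_moments((mm, np.zeros((3, 0)), Sm), sat, np.zeros((5, 0)))
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_cfi_drops_when_structural_paths_wrongly_zeroed(self, spec, params, mar_cohort):
        Y, W = mar_cohort.to_matrices(spec)
        sat = saturated_fit((Y, W))
        base = baseline_fit(Y)
        nf = n_free_parameters(spec)
        ll_true = fiml_loglik(params, (Y, W), spec)
        p0 = params.copy()
        p0.B = np.zeros((9, 2))
        # keep the implied means centred where the data are
        p0.alpha_f = params.alpha_f + np.c_[params.B, np.zeros(9)] @ params.alpha_b
        ll_nopath = fiml_loglik(p0, (Y, W), spec)
        fi_true = fit_indices(ll_true, sat, base, n_free=nf,
                              model_moments=moment_maps(params, spec), W=W)
        fi_zero = fit_indices(ll_nopath, sat, base, n_free=nf,
                              model_moments=moment_maps(p0, spec), W=W)
        assert fi_zero.cfi < fi_true.cfi

    def test_nonpositive_df_rejected(self):
        sat = SaturatedResult(Pi=np.zeros((2, 1)), Sigma=np.eye(2), loglik=0.0,
                              n_params=5, n_iter=1, converged=True)
        base = baseline_fit(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_indices(-1.0, sat, base, n_free=5)

    def test_threshold_classification(self):
        assert classify_srmr(0.063) == "acceptable"
        assert classify_srmr(0.10) == "above"
        assert classify_cfi(0.91) == "below"
        assert classify_cfi(0.97) == "acceptable"


class _KnownVarianceMean:
    """Univariate mean with the variance fixed and known."""

    n_free = 1

    def __init__(self, v):
        self.v = v

    def moments(self, th):
        return (th[:1], np.zeros((1, 0), dtype=th.dtype),
                np.array([[self.v]], dtype=th.dtype))


class TestStandardErrors:
    def test_univariate_mean_se_closed_form(self):
        rng = np.random.default_rng(5)
        v, n = 2.5, 80
        Y = rng.normal(1.0, np.sqrt(v), size=(n, 1))
        W = np.zeros((n, 0))
        model = _KnownVarianceMean(v)
        pf = fit_moment_model(model, Y, W, np.array([0.0]),
                              FitOptions(starts=1, precondition=False))
        for method in ("expected", "observed"):
            se = standard_errors(model, Y, W, pf.theta, method=method)
            np.testing.assert_allclose(se[0], np.sqrt(v / n), rtol=1e-4)

    def test_expected_and_observed_information_agree_at_optimum(self, spec, params, complete_cohort):
        """Two independent information routes (closed-form Fisher vs
        numerical Hessian of the likelihood) give matching SEs for the
        well-identified structural paths."""
        Y, W = complete_cohort.to_matrices(spec)
        opts = FitOptions(starts=1, compute_se=False, compute_indices=False)
        res = fit(complete_cohort, spec, init=params, options=opts)
        model = JointMomentModel(spec)
        se_e = standard_errors(model, Y, W, res.theta, method="expected")
        se_o = standard_errors(model, Y, W, res.theta, method="observed")
        for nm in ("B[g0<-b0]", "B[c0<-b0]", "B[h0<-b0]", "lam[glu2h]"):
            i = res.se_names.index(nm)
            assert np.isfinite(se_o[i])
            assert abs(se_e[i] - se_o[i]) / se_o[i] < 0.25

    def test_se_invariant_to_participant_order(self, spec, params, complete_cohort):
        Y, W = complete_cohort.to_matrices(spec)
        model = JointMomentModel(spec)
        th = pack_parameters(params, spec)
        perm = np.random.default_rng(2).permutation(Y.shape[0])
        se1 = standard_errors(model, Y, W, th)
        se2 = standard_errors(model, Y[perm], W[perm], th)
        np.testing.assert_allclose(se1, se2, rtol=1e-8)


class TestFit:
    def test_grid_search_oracle_on_two_variable_factor_model(self):
        """Quasi-Newton FIML agrees with an exhaustive grid search on a
        4-parameter single-factor model (two indicators, known residual
        variance)."""
        rng = np.random.default_rng(8)
        n = 150
        m1, m2, lam, psi, theta = 0.5, -0.3, 1.4, 0.9, 0.5
        eta = rng.normal(0, np.sqrt(psi), n)
        Y = np.column_stack([
            m1 + eta + rng.normal(0, np.sqrt(theta), n),
            m2 + lam * eta + rng.normal(0, np.sqrt(theta), n),
        ])
        W = np.zeros((n, 0))

        class OneFactor:
            n_free = 4

            def moments(self, th):
                m = th[:2]
                lv = th[2]
                p = np.exp(th[3])
                S = np.array([[p + theta, lv * p],
                              [lv * p, lv**2 * p + theta]], dtype=th.dtype)
                return m, np.zeros((2, 0), dtype=th.dtype), S

        pf = fit_moment_model(OneFactor(), Y, W, np.array([0.0, 0.0, 1.0, 0.0]),
                              FitOptions(starts=1, tol=1e-12))

        # brute-force grid oracle over the 4-d parameter box
        ybar = Y.mean(axis=0)
        S_emp = (Y - ybar).T @ (Y - ybar) / n
        g1 = np.linspace(0.2, 0.9, 36)
        g2 = np.linspace(-0.6, 0.0, 36)
        gl = np.linspace(1.0, 1.9, 36)
        gp = np.linspace(np.log(0.5), np.log(1.5), 36)
        best = (-np.inf, None)
        for lv in gl:
            for lp in gp:
                p = np.exp(lp)
                S = np.array([[p + theta, lv * p], [lv * p, lv**2 * p + theta]])
                Sinv = np.linalg.inv(S)
                _, logdet = np.linalg.slogdet(S)
                base_ll = -0.5 * n * (2 * np.log(2 * np.pi) + logdet
                                      + np.trace(Sinv @ S_emp))
                for a in g1:
                    for b in g2:
                        d = ybar - [a, b]
                        ll = base_ll - 0.5 * n * d @ Sinv @ d
                        if ll > best[0]:
                            best = (ll, (a, b, lv, lp))
        step = np.array([g1[1] - g1[0], g2[1] - g2[0], gl[1] - gl[0], gp[1] - gp[0]])
        est = pf.theta
        assert pf.loglik >= best[0] - 1e-9
        assert np.all(np.abs(est - np.asarray(best[1])) <= step + 1e-9)

    def test_low_noise_recovery_of_growth_factor_means(self, spec, params):
        """With variances shrunk, the fitted growth-factor means
        reproduce the generating values closely."""
        from metatraj.cohort import MissingnessConfig, generate_cohort
        from metatraj.simulate import AlertThresholds

        p = params.copy()
        p.Psi_b = params.Psi_b * 0.01
        p.Psi_zeta = params.Psi_zeta * 0.01
        p.omega = params.omega * 0.01
        p.theta = params.theta * 0.01
        cohort, _ = generate_cohort(250, p, spec,
                                    missingness=MissingnessConfig.none(),
                                    thresholds=AlertThresholds.none(), seed=17)
        res = fit(cohort, spec, init=p,
                  options=FitOptions(starts=1, compute_se=False,
                                     compute_indices=False))
        assert res.converged
        np.testing.assert_allclose(res.estimates.alpha_b, p.alpha_b,
                                   rtol=0.02, atol=0.02)
        # mean structure (growth-factor means through the paths) reproduced
        mu_hat = implied_moments(res.estimates, np.zeros(6), spec).mu
        mu_true = implied_moments(p, np.zeros(6), spec).mu
        np.testing.assert_allclose(mu_hat, mu_true, rtol=0.01, atol=0.05)


def test_fisher_information_matches_hessian_on_toy():
    """Expected information equals the closed-form values for the Gaussian
    mean/variance toy (n/v and n/2 in the log-variance metric)."""
    rng = np.random.default_rng(0)
    n = 40
    Y = rng.normal(1.0, 2.0, size=(n, 1))
    W = np.zeros((n, 0))

    class MeanLogVar:
        n_free = 2

        def moments(self, th):
            return (th[:1], np.zeros((1, 0), dtype=th.dtype),
                    np.exp(th[1]).reshape(1, 1))

    th = np.array([0.7, np.log(3.2)])
    pats = prepare_patterns(Y, W)
    I = expected_information(MeanLogVar(), th, pats, 0)
    np.testing.assert_allclose(I, np.diag([n / 3.2, n / 2.0]), atol=1e-8)
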