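"""Variational engine: conjugate updates, ELBO, empirical-Bayes M-steps."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal

from mrmash import (
    CovSpec,
    FitOptions,
    MixturePrior,
    build_prior,
    compute_elbo,
    fit_mrmash_rss,
    posterior_per_variant,
    scenario_config,
    simulate_scenario,
    suffstats_from_individual,
    update_V,
    update_w0,
)
from mrmash.engine import _WhitenedPrior, _safe_log, _variant_update


def _single_component_prior(S0):
    S0 = np.asarray(S0, dtype=float)
    return MixturePrior(w0=np.array([1.0]), S0=S0[None], labels=["only"])


class TestPosteriorPerVariant:
    def test_null_component_shrinks_to_zero(self, rng):
        prior = MixturePrior(w0=np.array([1.0]), S0=np.zeros((1, 2, 2)),
                             labels=["null"])
        b_hat = rng.standard_normal(2)
        gamma, mu1, Sigma1, b_bar, M2 = posterior_per_variant(
            b_hat, 5.0, np.eye(2), prior)
        assert np.all(mu1[0] == 0) and np.all(Sigma1[0] == 0)
        assert np.all(b_bar == 0) and np.all(M2 == 0)

    def test_scalar_conjugate_closed_form(self):
        prior = _single_component_prior([[1.0]])
        gamma, mu1, Sigma1, b_bar, _ = posterior_per_variant(
            np.array([1.0]), 10.0, np.array([[1.0]]), prior)
        assert mu1[0][0] == pytest.approx(10 / 11, rel=1e-12)
        assert Sigma1[0][0, 0] == pytest.approx(1 / 11, rel=1e-12)
        assert b_bar[0] == pytest.approx(10 / 11, rel=1e-12)

    def test_component_evidence_matches_quadrature(self):
        # the marginal N(b̂; 0, S0 + V/d) must equal the convolution
        # ∫ N(b̂; b, V/d) N(b; 0, S0) db, here checked by 2-D quadrature
        S0 = np.array([[1.0, 0.5], [0.5, 0.8]])
        V = np.array([[1.0, 0.2], [0.2, 1.5]])
        d = 4.0
        b_hat = np.array([0.7, -0.3])
        closed = multivariate_normal(cov=S0 + V / d).pdf(b_hat)
        lik = multivariate_normal(cov=V / d)
        pri = multivariate_normal(cov=S0)

        def integrand(b2, b1):
            b = np.array([b1, b2])
            return lik.pdf(b_hat - b) * pri.pdf(b)

        quad, _ = integrate.dblquad(integrand, -6, 6, -6, 6,
                                    epsabs=1e-10, epsrel=1e-10)
        assert quad == pytest.approx(closed, rel=1e-6)

    def test_duplicated_components_share_responsibility(self, rng):
        S = np.array([[0.5, 0.1], [0.1, 0.5]])
        prior = MixturePrior(
            w0=np.array([0.5, 0.5]), S0=np.stack([S, S]), labels=["a", "b"])
        gamma, *_ = posterior_per_variant(rng.standard_normal(2), 3.0,
                                          np.eye(2), prior)
        assert gamma[0] == pytest.approx(gamma[1], rel=1e-12)

    def test_fast_path_agrees_with_reference(self, rng):
        prior = build_prior(3, CovSpec(scale_grid=np.array([0.05, 0.5, 2.0])))
        V = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        wp = _WhitenedPrior(prior, V)
        logw0 = _safe_log(prior.w0)
        for _ in range(10):
            b_hat = rng.standard_normal(3)
            d = float(rng.uniform(0.5, 50))
            g_ref, _, _, b_ref, M2_ref = posterior_per_variant(b_hat, d, V, prior)
            g, btbar, M2t, _, _ = _variant_update(wp.Linv @ b_hat, d, wp, logw0)
            assert np.max(np.abs(g - g_ref)) < 1e-10
            assert np.max(np.abs(wp.L @ btbar - b_ref)) < 1e-10
            assert np.max(np.abs(wp.L @ M2t @ wp.L.T - M2_ref)) < 1e-10

    def test_shrinkage_monotone_in_prior_variance_and_d(self):
        V = np.array([[1.0]])
        b_hat = np.array([1.0])
        norms_s = [
            abs(posterior_per_variant(b_hat, 5.0, V,
                                      _single_component_prior([[s0]]))[3][0])
            for s0 in (0.1, 0.5, 1.0, 5.0)
        ]
        assert np.all(np.diff(norms_s) > 0)
        norms_d = [
            abs(posterior_per_variant(b_hat, d, V,
                                      _single_component_prior([[0.5]]))[3][0])
            for d in (1.0, 5.0, 25.0, 125.0)
        ]
        assert np.all(np.diff(norms_d) > 0)


class TestFit:
    def test_null_only_prior_gives_zero_effects(self, small_dataset):
        X, Y, _ = small_dataset
        ss = suffstats_from_individual(X, Y)
        prior = MixturePrior(w0=np.array([1.0]), S0=np.zeros((1, 3, 3)),
                             labels=["null"])
        fit = fit_mrmash_rss(ss, prior, opts=FitOptions(update_w0=False))
        assert np.all(fit.B_bar == 0)
        assert fit.converged and fit.n_iter <= 2
        # ELBO equals the null-model log likelihood term
        expected = (
            -0.5 * ss.n * ss.r * np.log(2 * np.pi)
            - 0.5 * ss.n * np.linalg.slogdet(fit.V_fit)[1]
            - 0.5 * np.trace(np.linalg.solve(fit.V_fit, ss.YtY))
        )
        assert fit.elbo_trace[-1] == pytest.approx(expected, rel=1e-10)

    def test_ridge_fixed_point(self, rng):
        n, p = 200, 10
        X = rng.standard_normal((n, p))
        y = X @ (rng.standard_normal(p) * 0.3) + rng.standard_normal(n)
        ss = suffstats_from_individual(X, y[:, None], center=True)
        s0, v = 0.5, 1.3
        prior = MixturePrior(w0=np.array([0.0, 1.0]),
                             S0=np.array([[[0.0]], [[s0]]]),
                             labels=["null", "ridge"])
        opts = FitOptions(tol=1e-14, max_iter=2000, update_w0=False)
        fit = fit_mrmash_rss(ss, prior, V_init=np.array([[v]]), opts=opts)
        ridge = np.linalg.solve(ss.XtX + (v / s0) * np.eye(p), ss.XtY)
        assert np.max(np.abs(fit.B_bar - ridge)) < 1e-6

    def test_conjugate_evidence_single_variant(self, rng):
        # with one variant, one phenotype and one Gaussian component the
        # variational posterior is exact, so the ELBO must equal the exact
        # log marginal likelihood of y ~ N(0, s0 x xᵀ + v I)
        n, s0, v = 60, 0.7, 1.0
        x = rng.standard_normal(n)
        x -= x.mean()
        y = 0.4 * x + rng.standard_normal(n)
        y -= y.mean()
        ss = suffstats_from_individual(x[:, None], y[:, None], center=False)
        prior = _single_component_prior([[s0]])
        fit = fit_mrmash_rss(ss, prior, V_init=np.array([[v]]),
                             opts=FitOptions(update_w0=False, max_iter=5))
        Sigma = s0 * np.outer(x, x) + v * np.eye(n)
        exact = multivariate_normal(cov=Sigma, allow_singular=False).logpdf(y)
        assert fit.elbo_trace[-1] == pytest.approx(exact, rel=1e-10)

    def test_elbo_is_state_function_not_path_function(self, small_dataset):
        X, Y, _ = small_dataset
        ss = suffstats_from_individual(X, Y)
        prior = build_prior(3, CovSpec(scale_grid=np.array([1e-3, 1e-2, 1e-1])))
        fits = [
            fit_mrmash_rss(ss, prior, opts=FitOptions(
                max_iter=6, update_order=order, seed=11))
            for order in ("fixed", "shuffled")
        ]
        for fit in fits:
            recomputed = compute_elbo(
                ss, fit.bhat, prior.with_weights(fit.w0_fit), fit.V_fit)
            assert recomputed == pytest.approx(fit.elbo_trace[-1], rel=1e-10)

    def test_equal_effects_parameter_recovery(self):
        sim = simulate_scenario(scenario_config(
            "equal_effects", n_train=600, n_test=10, p=120, n_causal=8,
            r=3, h2=np.full(3, 0.8), seed=5))
        Y = sim.Y_train - sim.Y_train.mean(0)
        Y /= Y.std(0, ddof=1)
        ss = suffstats_from_individual(sim.X_train, Y)
        prior = build_prior(3, CovSpec(scale_grid=np.logspace(-4, 0, 10)))
        fit = fit_mrmash_rss(ss, prior, opts=FitOptions(update_V=True,
                                                        max_iter=200))
        c = np.corrcoef(fit.B_bar.ravel(), sim.B_true.ravel())[0, 1]
        assert c > 0.8

    def test_update_v_requires_yty(self, small_dataset):
        X, Y, _ = small_dataset
        ss = suffstats_from_individual(X, Y)
        ss.YtY = None
        prior = build_prior(3, CovSpec(scale_grid=np.array([0.01])))
        with pytest.raises(ValueError, match="V fixed"):
            fit_mrmash_rss(ss, prior, opts=FitOptions(update_V=True))


class TestMSteps:
    def test_update_w0_constant_and_onehot_rows(self):
        gamma = np.tile([0.3, 0.7], (20, 1))
        assert np.allclose(update_w0(gamma), [0.3, 0.7])
        assert np.allclose(update_w0(np.eye(4)), np.full(4, 0.25))

    def test_update_w0_is_local_optimum_of_weight_term(self, rng):
        gamma = rng.dirichlet(np.ones(4), size=30)
        w = update_w0(gamma)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

        def weight_term(wv):
            return float(np.sum(gamma * np.log(wv)))

        base = weight_term(w)
        for _ in range(20):
            pert = np.clip(w + rng.uniform(-1e-3, 1e-3, 4), 1e-9, None)
            pert /= pert.sum()
            assert weight_term(pert) <= base + 1e-12

    def test_update_v_null_model_residuals(self, small_dataset):
        X, Y, _ = small_dataset
        ss = suffstats_from_individual(X, Y)
        V = update_V(ss, np.zeros((ss.p, ss.r)), np.zeros((ss.r, ss.r)))
        assert np.allclose(V, ss.YtY / ss.n)

    def test_update_v_symmetric_floored(self, rng):
        from mrmash import SufficientStats

        for _ in range(5):
            A = rng.standard_normal((30, 8))
            Yv = rng.standard_normal((30, 2))
            ss = suffstats_from_individual(A, Yv)
            B = rng.standard_normal((8, 2)) * 0.1
            dsum = rng.standard_normal((2, 2))
            dsum = dsum @ dsum.T
            V = update_V(ss, B, dsum)
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() >= 1e-8 - 1e-15

    def test_update_v_recovers_true_residual_covariance(self, rng):
        n, p, r = 500, 20, 2
        V_star = np.array([[1.0, 0.5], [0.5, 2.0]])
        X = rng.binomial(2, 0.4, (n, p)).astype(float)
        B = rng.standard_normal((p, r)) * 0.5
        E = rng.standard_normal((n, r)) @ np.linalg.cholesky(V_star).T
        Y = X @ B + E
        ss = suffstats_from_individual(X, Y)
        prior = build_prior(r, CovSpec(scale_grid=np.logspace(-2, 1, 10)))
        fit = fit_mrmash_rss(ss, prior, opts=FitOptions(update_V=True,
                                                        max_iter=300))
        err = np.linalg.norm(fit.V_fit - V_star) / np.linalg.norm(V_star)
        assert err < 0.15
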