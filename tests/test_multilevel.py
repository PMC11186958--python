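from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from popergm.ergm import AuxSamplerConfig, simulate_ergm
from popergm.multilevel import (
    PopulationData,
    PopulationState,
    PriorHyper,
    SamplerConfig,
    _GibbsRuntime,
    conjugate_posterior,
    default_prior,
    gibbs_step_asis,
    gibbs_step_cp,
    run_sampler,
    sample_beta,
    sample_sigma,
)
from popergm.netstats import Graph, StatisticSpec

from .conftest import random_graph


@pytest.fixture(scope="module")
def tiny_population():
    """n = 3 small edges-only networks with an intercept design."""
    rng = np.random.default_rng(9)
    spec = StatisticSpec.from_strings(["edges"])
    tmpl = Graph.empty(5)
    aux = AuxSamplerConfig(n_aux=2000, init_mode="random")
    theta = np.array([[-0.5], [0.0], [0.5]])
    nets = [simulate_ergm(theta[i], spec, tmpl, aux, rng) for i in range(3)]
    return PopulationData(networks=nets, X=np.ones((3, 1)), spec=spec)


class TestDefaultPrior:
    def test_paper_defaults_p3_q1(self):
        prior = default_prior(p=3, q=1)
        np.testing.assert_array_equal(prior.beta0, np.zeros((1, 3)))
        np.testing.assert_allclose(prior.lambda0, [[0.01]])
        np.testing.assert_array_equal(prior.V0, np.eye(3))
        assert prior.nu0 == 4

    def test_scalar_case(self):
        prior = default_prior(p=1, q=1)
        assert prior.beta0[0, 0] == 0.0
        assert prior.lambda0[0, 0] == pytest.approx(0.01)
        assert prior.V0[0, 0] == 1.0
        assert prior.nu0 == 2

    def test_prior_beta_marginal_variance(self, rng):
        # under the matrix-normal prior, var(beta_jk | Sigma) = 100 Sigma_kk
        prior = default_prior(p=2, q=1)
        sigma = np.diag([0.5, 2.0])
        hyper = conjugate_posterior(np.empty((0, 2)), np.empty((0, 1)), prior)
        draws = np.array([sample_beta(hyper, sigma, rng) for _ in range(20000)])
        np.testing.assert_allclose(
            draws[:, 0, :].var(axis=0), [50.0, 200.0], rtol=0.1
        )

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            default_prior(0, 1)


class TestConjugatePosterior:
    def test_n_zero_returns_prior(self):
        prior = default_prior(p=2, q=2)
        post = conjugate_posterior(np.empty((0, 2)), np.empty((0, 2)), prior)
        np.testing.assert_array_equal(post.lambda_n, prior.lambda0)
        np.testing.assert_array_equal(post.beta_n, prior.beta0)
        np.testing.assert_array_equal(post.V_n, prior.V0)
        assert post.nu_n == prior.nu0

    def test_hand_computed_scalar_example(self):
        # X = (1,1)', theta = (1,3)', beta0 = 0, Lambda0 = 1, V0 = 1, nu0 = 3
        prior = PriorHyper(
            beta0=np.zeros((1, 1)),
            lambda0=np.eye(1),
            V0=np.eye(1),
            nu0=3.0,
        )
        post = conjugate_posterior(
            np.array([[1.0], [3.0]]), np.ones((2, 1)), prior
        )
        assert post.lambda_n[0, 0] == 3.0
        assert Fraction(post.beta_n[0, 0]).limit_denominator(100) == Fraction(4, 3)
        assert post.nu_n == 5.0
        assert Fraction(post.V_n[0, 0]).limit_denominator(100) == Fraction(17, 3)

    def test_flat_limit_is_ols(self, rng):
        X = rng.standard_normal((20, 2))
        theta = rng.standard_normal((20, 3))
        prior = PriorHyper(
            beta0=np.zeros((2, 3)),
            lambda0=1e-10 * np.eye(2),
            V0=np.eye(3),
            nu0=4.0,
        )
        post = conjugate_posterior(theta, X, prior)
        ols = np.linalg.lstsq(X, theta, rcond=None)[0]
        np.testing.assert_allclose(post.beta_n, ols, atol=1e-6)

    def test_lambda_increment_is_gram(self, rng):
        X = rng.standard_normal((7, 2))
        prior = default_prior(p=1, q=2)
        post = conjugate_posterior(rng.standard_normal((7, 1)), X, prior)
        np.testing.assert_allclose(post.lambda_n - prior.lambda0, X.T @ X)

    def test_vn_positive_definite(self, rng):
        prior = default_prior(p=3, q=2)
        post = conjugate_posterior(
            rng.standard_normal((10, 3)), rng.standard_normal((10, 2)), prior
        )
        assert np.all(np.linalg.eigvalsh(post.V_n) > 0)


class TestSampleBeta:
    def test_mean_recovery(self, rng):
        prior = default_prior(p=2, q=2)
        X = rng.standard_normal((30, 2))
        theta = rng.standard_normal((30, 2))
        post = conjugate_posterior(theta, X, prior)
        draws = np.array(
            [sample_beta(post, np.eye(2), rng) for _ in range(5000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), post.beta_n, atol=0.05)

    def test_kronecker_covariance(self, rng):
        # cov(vec(B')) = Lambda_n^-1 (x) Sigma for row-major vec
        from popergm.multilevel import PosteriorHyper

        lam = np.array([[2.0, 0.5], [0.5, 1.0]])
        sig = np.array([[1.0, -0.3], [-0.3, 0.5]])
        post = PosteriorHyper(
            beta_n=np.zeros((2, 2)), lambda_n=lam, V_n=np.eye(2), nu_n=10.0
        )
        draws = np.array(
            [sample_beta(post, sig, rng).ravel() for _ in range(40000)]
        )
        expected = np.kron(np.linalg.inv(lam), sig)
        np.testing.assert_allclose(np.cov(draws.T), expected, atol=0.05)


class TestSampleSigma:
    def test_scalar_is_inverse_gamma(self, rng):
        from popergm.multilevel import PosteriorHyper

        post = PosteriorHyper(
            beta_n=np.zeros((1, 1)),
            lambda_n=np.eye(1),
            V_n=np.array([[3.0]]),
            nu_n=8.0,
        )
        draws = np.array([sample_sigma(post, rng)[0, 0] for _ in range(5000)])
        # IW(V, nu) with p = 1 is InvGamma(nu/2, V/2)
        ks = stats.kstest(draws, stats.invgamma(a=4.0, scale=1.5).cdf)
        assert ks.pvalue > 0.01

    def test_mean_matches_closed_form(self, rng):
        from popergm.multilevel import PosteriorHyper

        V = np.array([[2.0, 0.3], [0.3, 1.0]])
        post = PosteriorHyper(
            beta_n=np.zeros((1, 2)), lambda_n=np.eye(1), V_n=V, nu_n=12.0
        )
        draws = np.array([sample_sigma(post, rng) for _ in range(8000)])
        np.testing.assert_allclose(
            draws.mean(axis=0), V / (12.0 - 2 - 1), rtol=0.1
        )

    def test_wishart_duality(self, rng):
        from popergm.multilevel import PosteriorHyper

        V = np.array([[1.5]])
        post = PosteriorHyper(
            beta_n=np.zeros((1, 1)), lambda_n=np.eye(1), V_n=V, nu_n=9.0
        )
        inv_draws = np.array(
            [1.0 / sample_sigma(post, rng)[0, 0] for _ in range(8000)]
        )
        # inverses follow Wishart(V^-1, nu): mean nu * V^-1
        assert inv_draws.mean() == pytest.approx(9.0 / 1.5, rel=0.05)

    def test_invalid_dof(self):
        from popergm.multilevel import PosteriorHyper

        post = PosteriorHyper(
            beta_n=np.zeros((1, 2)), lambda_n=np.eye(1), V_n=np.eye(2), nu_n=0.5
        )
        with pytest.raises(ValueError):
            sample_sigma(post, np.random.default_rng(0))


class TestGibbsSteps:
    def _runtime(self, data, cfg):
        return _GibbsRuntime(data, cfg)

    def test_conditional_draws_reproduce_conjugate_moments(self, tiny_population):
        # with theta held fixed, repeated (beta, sigma) redraws follow
        # the conjugate conditional posterior
        data = tiny_population
        prior = default_prior(p=1, q=1)
        cfg = SamplerConfig(
            n_iter=10, burn_in=1, aux=AuxSamplerConfig(n_aux=10), rng_seed=4
        )
        rt = self._runtime(data, cfg)
        theta = np.array([[-0.4], [0.1], [0.6]])
        post = conjugate_posterior(theta, data.X, prior)
        betas = []
        for _ in range(4000):
            sig = sample_sigma(post, rt.rng_gibbs)
            betas.append(sample_beta(post, sig, rt.rng_gibbs)[0, 0])
        betas = np.asarray(betas)
        assert betas.mean() == pytest.approx(post.beta_n[0, 0], abs=0.05)

    def test_asis_preserves_state_identity(self, tiny_population):
        data = tiny_population
        prior = default_prior(p=1, q=1)
        cfg = SamplerConfig(
            n_iter=10, burn_in=1, aux=AuxSamplerConfig(n_aux=50), rng_seed=4
        )
        rt = self._runtime(data, cfg)
        state = PopulationState(
            theta=np.zeros((3, 1)),
            beta=np.zeros((1, 1)),
            sigma_eps=np.eye(1),
            X=data.X,
        )
        for _ in range(5):
            gibbs_step_asis(state, data, prior, rt, cfg)
            np.testing.assert_allclose(
                state.theta, state.mu + state.epsilon, atol=1e-12
            )

    def test_asis_with_zero_ncp_scale_equals_cp(self, tiny_population):
        data = tiny_population
        prior = default_prior(p=1, q=1)
        cfg = SamplerConfig(
            n_iter=10, burn_in=1, aux=AuxSamplerConfig(n_aux=50), rng_seed=4
        )
        rt_a = self._runtime(data, cfg)
        rt_b = self._runtime(data, cfg)
        rt_b.prop_beta.log_delta = -80.0  # NCP proposal collapses to current
        state_a = PopulationState(
            np.zeros((3, 1)), np.zeros((1, 1)), np.eye(1), data.X
        )
        state_b = state_a.copy()
        for _ in range(3):
            gibbs_step_cp(state_a, data, prior, rt_a, cfg)
            gibbs_step_asis(state_b, data, prior, rt_b, cfg)
        np.testing.assert_allclose(state_a.beta, state_b.beta, atol=1e-10)


class TestRunSampler:
    def test_single_kept_draw(self, tiny_population):
        cfg = SamplerConfig(
            n_iter=6,
            burn_in=5,
            aux=AuxSamplerConfig(n_aux=20),
            rng_seed=0,
            adapt_window=4,
        )
        prior = default_prior(p=1, q=1)
        samples = run_sampler(tiny_population, prior, cfg)
        assert samples.n_draws == 1

    def test_seed_repeatability(self, tiny_population):
        cfg = SamplerConfig(
            n_iter=60,
            burn_in=10,
            aux=AuxSamplerConfig(n_aux=30),
            rng_seed=123,
            adapt_window=40,
        )
        prior = default_prior(p=1, q=1)
        s1 = run_sampler(tiny_population, prior, cfg)
        s2 = run_sampler(tiny_population, prior, cfg)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.sigma_eps, s2.sigma_eps)
        np.testing.assert_array_equal(s1.theta, s2.theta)

    def test_thinning(self, tiny_population):
        cfg = SamplerConfig(
            n_iter=30,
            burn_in=10,
            thinning=4,
            aux=AuxSamplerConfig(n_aux=20),
            rng_seed=0,
            adapt_window=20,
        )
        samples = run_sampler(tiny_population, default_prior(1, 1), cfg)
        assert samples.n_draws == 5

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=10, burn_in=10)
        with pytest.raises(ValueError):
            SamplerConfig(parameterization="hmc")

    def test_prior_dimension_mismatch(self, tiny_population):
        cfg = SamplerConfig(n_iter=4, burn_in=1, aux=AuxSamplerConfig(n_aux=5))
        with pytest.raises(ValueError):
            run_sampler(tiny_population, default_prior(p=2, q=1), cfg)

    def test_cross_parameterization_agreement(self, tiny_population):
        # CP, NCP and ASIS chains target the same posterior
        prior = default_prior(p=1, q=1)
        means, mcses = {}, {}
        for param in ("cp", "ncp", "asis"):
            cfg = SamplerConfig(
                n_iter=5000,
                burn_in=1000,
                parameterization=param,
                aux=AuxSamplerConfig(n_aux=300),
                rng_seed=2,
                adapt_window=1000,
            )
            s = run_sampler(tiny_population, prior, cfg)
            b = s.beta[:, 0, 0]
            nb = 40
            bm = b[: b.size // nb * nb].reshape(nb, -1).mean(axis=1)
            means[param] = b.mean()
            mcses[param] = bm.std() / np.sqrt(nb)
        for a in ("cp", "ncp"):
            for b_ in ("ncp", "asis"):
                if a == b_:
                    continue
                tol = 3 * np.hypot(mcses[a], mcses[b_])
                assert abs(means[a] - means[b_]) < tol


class TestJointCorrectness:
    def test_geweke_successive_conditional(self):
        # alternating forward data simulation and Gibbs parameter
        # updates must leave the prior law of (beta, Sigma) invariant
        rng = np.random.default_rng(123)
        spec = StatisticSpec.from_strings(["edges"])
        tmpl = Graph.empty(4)
        n = 2
        X = np.ones((n, 1))
        prior = PriorHyper(
            beta0=np.zeros((1, 1)), lambda0=np.eye(1), V0=np.eye(1), nu0=6.0
        )
        cfg = SamplerConfig(
            n_iter=10,
            burn_in=1,
            aux=AuxSamplerConfig(n_aux=300, init_mode="observed"),
            rng_seed=0,
            adapt_window=10**9,
        )
        gen_aux = AuxSamplerConfig(n_aux=800, init_mode="random")

        sig0 = stats.invwishart.rvs(df=prior.nu0, scale=prior.V0, random_state=rng)
        beta0 = np.sqrt(sig0) * rng.standard_normal((1, 1))
        theta0 = X @ beta0 + np.sqrt(sig0) * rng.standard_normal((n, 1))
        state = PopulationState(
            theta=theta0, beta=beta0, sigma_eps=np.atleast_2d(sig0), X=X
        )
        data = PopulationData(
            networks=[tmpl.copy() for _ in range(n)], X=X, spec=spec
        )
        rt = _GibbsRuntime(data, cfg)
        betas, sigmas = [], []
        for _ in range(4000):
            nets = [
                simulate_ergm(state.theta[i], spec, tmpl, gen_aux, rng)
                for i in range(n)
            ]
            data = PopulationData(networks=nets, X=X, spec=spec)
            rt.s_obs = data.observed_stats()
            gibbs_step_cp(state, data, prior, rt, cfg)
            betas.append(state.beta[0, 0])
            sigmas.append(state.sigma_eps[0, 0])
        betas = np.asarray(betas)
        sigmas = np.asarray(sigmas)
        # prior moments: E beta = 0; var beta = E sigma * Lambda0^-1;
        # E sigma = V0 / (nu0 - 2) = 0.25
        nb = 50
        bm = betas[: betas.size // nb * nb].reshape(nb, -1).mean(axis=1)
        mcse = bm.std() / np.sqrt(nb)
        assert abs(betas.mean()) < 4 * max(mcse, 1e-3)
        assert sigmas.mean() == pytest.approx(0.25, rel=0.25)
        assert betas.var() == pytest.approx(0.25, rel=0.35)


class TestPosteriorSamplesApi:
    def test_credible_interval_shape(self, tiny_population):
        cfg = SamplerConfig(
            n_iter=40,
            burn_in=10,
            aux=AuxSamplerConfig(n_aux=20),
            rng_seed=0,
            adapt_window=20,
        )
        s = run_sampler(tiny_population, default_prior(1, 1), cfg)
        lo, hi = s.beta_credible_interval(0.9)
        assert lo.shape == (1, 1) and hi.shape == (1, 1)
        assert np.all(lo <= hi)

    def test_population_data_validation(self):
        spec = StatisticSpec.from_strings(["edges"])
        with pytest.raises(ValueError):
            PopulationData(networks=[], X=np.ones((0, 1)), spec=spec)
        with pytest.raises(ValueError):
            PopulationData(
                networks=[Graph.empty(4), Graph.empty(5)],
                X=np.ones((2, 1)),
                spec=spec,
            )
        with pytest.raises(ValueError):
            PopulationData(
                networks=[Graph.empty(4)], X=np.ones((2, 1)), spec=spec
            )
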