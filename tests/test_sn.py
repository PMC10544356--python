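import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm, skewnorm

from clrdv.sn import (
    SKEWNESS_BOUND,
    CenteredParams,
    DirectParams,
    cp_to_dp,
    dp_to_cp,
    fit_sn_cp,
    se_sigma_cp,
    sn_logpdf,
)


def random_cp(rng, gamma_max=0.99):
    return CenteredParams(
        mu=rng.uniform(-5, 5),
        sigma=rng.uniform(0.1, 5),
        gamma=rng.uniform(-gamma_max, gamma_max) * SKEWNESS_BOUND,
    )


class TestLogpdf:
    def test_alpha_zero_is_normal(self):
        x = np.linspace(-4, 7, 23)
        dp = DirectParams(1.5, 2.0, 0.0)
        assert np.allclose(sn_logpdf(x, dp), norm.logpdf(x, 1.5, 2.0))

    def test_value_at_location(self):
        for a in (-3.0, 0.0, 1.0, 10.0):
            assert sn_logpdf(0.0, DirectParams(0.0, 1.0, a)) == pytest.approx(
                norm.logpdf(0.0)
            )

    def test_integrates_to_one(self):
        dp = DirectParams(0.0, 1.0, 3.0)
        total, _ = integrate.quad(lambda t: np.exp(sn_logpdf(t, dp)), -15, 15)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_skewnorm(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        dp = DirectParams(0.3, 1.4, -2.1)
        assert np.allclose(
            sn_logpdf(x, dp), skewnorm.logpdf(x, dp.alpha, dp.xi, dp.omega)
        )


class TestParametrizationMaps:
    def test_symmetric_case_fixed_point(self):
        cp = dp_to_cp(DirectParams(1.2, 3.4, 0.0))
        assert (cp.mu, cp.sigma, cp.gamma) == (1.2, 3.4, 0.0)
        dp = cp_to_dp(CenteredParams(1.2, 3.4, 0.0))
        assert (dp.xi, dp.omega, dp.alpha) == (1.2, 3.4, 0.0)

    def test_moments_against_quadrature(self):
        # independent oracle: first three central moments by quadrature
        dp = DirectParams(0.0, 1.0, 1.0)
        pdf = lambda t: np.exp(sn_logpdf(t, dp))
        m1 = integrate.quad(lambda t: t * pdf(t), -12, 12)[0]
        m2 = integrate.quad(lambda t: (t - m1) ** 2 * pdf(t), -12, 12)[0]
        m3 = integrate.quad(lambda t: (t - m1) ** 3 * pdf(t), -12, 12)[0]
        cp = dp_to_cp(dp)
        assert cp.mu == pytest.approx(m1, abs=1e-8)
        assert cp.sigma == pytest.approx(math.sqrt(m2), abs=1e-8)
        assert cp.gamma == pytest.approx(m3 / m2**1.5, abs=1e-8)
        # frozen values for the same case
        assert cp.mu == pytest.approx(0.5642, abs=1e-4)
        assert cp.sigma == pytest.approx(0.8256, abs=1e-4)
        assert cp.gamma == pytest.approx(0.1370, abs=1e-4)

    def test_gamma_monotone_in_alpha_with_matching_sign(self):
        alphas = np.array([-50, -5, -1, -0.1, 0, 0.1, 1, 5, 50], dtype=float)
        gammas = [dp_to_cp(DirectParams(0, 1, a)).gamma for a in alphas]
        assert np.all(np.diff(gammas) > 0)
        assert np.all(np.sign(gammas) == np.sign(alphas))
        assert all(abs(g) < SKEWNESS_BOUND for g in gammas)

    def test_round_trip(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            cp = random_cp(rng)
            back = dp_to_cp(cp_to_dp(cp))
            worst = max(
                worst,
                abs(back.mu - cp.mu),
                abs(back.sigma - cp.sigma),
                abs(back.gamma - cp.gamma),
            )
        assert worst < 1e-8

    def test_boundary_gamma_rejected(self):
        with pytest.raises(ValueError):
            cp_to_dp(CenteredParams(0.0, 1.0, 0.9953))


class TestFit:
    def test_recovers_normal_sample(self):
        x = np.random.default_rng(1).normal(2.0, 1.0, size=10_000)
        fit = fit_sn_cp(x)
        assert fit.converged
        assert abs(fit.cp.mu - 2.0) < 4 * fit.se[0]
        assert abs(fit.cp.sigma - 1.0) < 4 * fit.se[1]
        assert abs(fit.cp.gamma - 0.0) < 4 * fit.se[2]

    def test_recovers_skewed_sample(self):
        true = CenteredParams(0.0, 1.0, 0.5)
        dp = cp_to_dp(true)
        x = skewnorm.rvs(dp.alpha, dp.xi, dp.omega, size=10_000, random_state=2)
        fit = fit_sn_cp(x)
        assert fit.converged and fit.method in ("mle", "penalized_q")
        assert abs(fit.cp.mu - true.mu) < 4 * fit.se[0]
        assert abs(fit.cp.sigma - true.sigma) < 4 * fit.se[1]
        assert abs(fit.cp.gamma - true.gamma) < 4 * fit.se[2]
        assert fit.var_sigma == pytest.approx(fit.se[1] ** 2)

    def test_loglik_not_below_normal_submodel(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            x = skewnorm.rvs(3.0, size=400, random_state=seed)
            fit = fit_sn_cp(x)
            s = np.std(x)
            normal_ll = np.sum(norm.logpdf(x, np.mean(x), s))
            assert fit.loglik >= normal_ll - 1e-6

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_sn_cp(np.full(100, 3.0))

    def test_minimum_length_enforced_and_small_n_warns(self):
        with pytest.raises(ValueError):
            fit_sn_cp(np.arange(10.0))
        with pytest.warns(UserWarning, match="unreliable"):
            fit_sn_cp(np.random.default_rng(4).normal(size=30))

    def test_extreme_sample_falls_down_ladder_with_flag(self):
        # half-normal-like data push alpha to the boundary under plain MLE
        x = np.abs(np.random.default_rng(5).normal(size=60))
        fit = fit_sn_cp(x)
        assert fit.converged
        assert abs(fit.cp.gamma) < SKEWNESS_BOUND


class TestSigmaSE:
    def test_normal_theory_limit(self):
        x = np.random.default_rng(6).normal(0.0, 2.0, size=10_000)
        fit = fit_sn_cp(x)
        expected = 2.0 / math.sqrt(2 * x.size)
        assert fit.se[1] == pytest.approx(expected, rel=0.10)

    def test_matches_independent_difference_scheme(self):
        true_dp = cp_to_dp(CenteredParams(1.0, 1.5, 0.3))
        x = skewnorm.rvs(
            true_dp.alpha, true_dp.xi, true_dp.omega, size=2_000, random_state=7
        )
        fit = fit_sn_cp(x)
        # independent oracle: hand-rolled central-difference Hessian of the
        # CP negative log-likelihood
        def nll(mu, sigma, gamma):
            dp = cp_to_dp(CenteredParams(mu, sigma, gamma))
            return -np.sum(sn_logpdf(x, dp))

        p0 = np.array([fit.cp.mu, fit.cp.sigma, fit.cp.gamma])
        h = 1e-4 * np.maximum(np.abs(p0), 0.1)
        hess = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                pp = p0.copy(); pp[i] += h[i]; pp[j] += h[j]
                pm = p0.copy(); pm[i] += h[i]; pm[j] -= h[j]
                mp = p0.copy(); mp[i] -= h[i]; mp[j] += h[j]
                mm = p0.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                hess[i, j] = (
                    nll(*pp) - nll(*pm) - nll(*mp) + nll(*mm)
                ) / (4 * h[i] * h[j])
        se_oracle = math.sqrt(np.linalg.inv(hess)[1, 1])
        assert se_sigma_cp(x, fit.cp) == pytest.approx(se_oracle, rel=1e-4)

    def test_se_shrinks_like_sqrt_n(self):
        dp = cp_to_dp(CenteredParams(0.0, 1.0, 0.4))
        x = skewnorm.rvs(dp.alpha, dp.xi, dp.omega, size=4_000, random_state=8)
        fit_half = fit_sn_cp(x[:2_000])
        fit_full = fit_sn_cp(x)
        ratio = fit_half.se[1] / fit_full.se[1]
        assert ratio == pytest.approx(math.sqrt(2), rel=0.15)
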