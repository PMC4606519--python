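import math

import numpy as np
import pytest
from scipy import integrate, stats

from bayesb.conditionals import (
    LocusSufficientStats,
    draw_beta_given_delta,
    draw_mu,
    draw_scaled_inv_chi2,
    draw_sigma2_e,
    draw_sigma2_j,
    log_marglik_univariate,
    prob_delta1_joint,
    prob_delta1_pseudo,
    prob_delta1_single_site,
    pseudo_prior_params,
)
from bayesb.data_model import Hyperparameters, ModelState


def bare_state(residual, mu=0.0, sigma2_e=1.0, k=0):
    return ModelState(
        mu=mu, beta=np.zeros(k), delta=np.zeros(k, dtype=np.int8),
        sigma2_j=np.ones(k), sigma2_e=sigma2_e,
        residual=np.asarray(residual, dtype=float),
    )


def brute_force_p1_single_site(w, x, beta, sigma2_e, pi):
    """Direct evaluation of (1-pi) d_j / ((1-pi) d_j + pi exp(-w'w/2s2e))."""
    d = math.exp(-float((w - x * beta) @ (w - x * beta)) / (2 * sigma2_e))
    e0 = math.exp(-float(w @ w) / (2 * sigma2_e))
    return (1 - pi) * d / ((1 - pi) * d + pi * e0)


def integrated_m1(rhs, xtx, sigma2_j, sigma2_e):
    """m1 by numerically integrating f(rhs | beta) N(beta; 0, sigma2_j)."""
    sd_b = math.sqrt(sigma2_j)

    def integrand(b):
        return stats.norm.pdf(rhs, loc=xtx * b, scale=math.sqrt(xtx * sigma2_e)) \
            * stats.norm.pdf(b, scale=sd_b)

    val, _ = integrate.quad(integrand, -12 * sd_b, 12 * sd_b, limit=200)
    return val


class TestScaledInvChi2:
    def test_invalid_args(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            draw_scaled_inv_chi2(-1, 1, rng)
        with pytest.raises(ValueError):
            draw_scaled_inv_chi2(4, 0, rng)

    def test_construction_matches_definition(self):
        # nu=4, S2=2 -> draw is 8 / chi2_4 for the same chi-square variate
        d = draw_scaled_inv_chi2(4, 2, np.random.default_rng(123))
        chi = np.random.default_rng(123).chisquare(4)
        assert d == pytest.approx(8.0 / chi, rel=1e-15)

    def test_monte_carlo_mean(self):
        # closed form: mean = nu*S2/(nu-2) = 30/8 = 3.75 for nu=10, S2=3
        rng = np.random.default_rng(2024)
        n = 200_000
        draws = 10 * 3 / rng.chisquare(10, n)  # vectorized same construction
        single = np.array([draw_scaled_inv_chi2(10, 3, np.random.default_rng(s)) for s in range(2000)])
        # scalar API agrees in distribution with the vectorized oracle
        true_mean = 30 / 8
        var = 2 * 10**2 * 3**2 / ((10 - 2) ** 2 * (10 - 4))
        assert abs(draws.mean() - true_mean) < 3 * math.sqrt(var / n)
        assert abs(single.mean() - true_mean) < 4 * math.sqrt(var / len(single))

    def test_monte_carlo_median(self):
        # quantile transform: median = nu*S2/median(chi2_nu)
        rng = np.random.default_rng(7)
        n = 100_000
        draws = 4 * 1 / rng.chisquare(4, n)
        true_median = 4.0 / stats.chi2.median(4)
        assert np.median(draws) == pytest.approx(true_median, rel=0.02)


class TestDrawMu:
    def test_hand_parameters_seed_matched(self):
        # e_mu = [1, 3], sigma2_e = 4 -> N(2, 2)
        state = bare_state([1.0, 3.0], mu=0.0, sigma2_e=4.0)
        got = draw_mu(state, np.random.default_rng(5))
        z = np.random.default_rng(5).standard_normal()
        assert got == pytest.approx(2.0 + math.sqrt(2.0) * z, rel=1e-12)
        # residual now reflects the new mu
        np.testing.assert_allclose(state.residual, np.array([1.0, 3.0]) - got)

    def test_monte_carlo_moments(self):
        rng = np.random.default_rng(11)
        n_rep = 20_000
        draws = np.empty(n_rep)
        for i in range(n_rep):
            state = bare_state([1.0, 3.0], mu=0.0, sigma2_e=4.0)
            draws[i] = draw_mu(state, rng)
        assert abs(draws.mean() - 2.0) < 3 * math.sqrt(2.0 / n_rep)
        assert abs(draws.var(ddof=1) - 2.0) < 3 * 2.0 * math.sqrt(2.0 / n_rep)

    def test_degenerate_small_variance(self):
        state = bare_state([1.0, 3.0], mu=0.0, sigma2_e=1e-20)
        assert draw_mu(state, np.random.default_rng(0)) == pytest.approx(2.0, abs=1e-8)

    def test_proper_prior_shrinks(self):
        # huge prior precision pins mu at the prior mean
        state = bare_state([1.0, 3.0], mu=0.0, sigma2_e=4.0)
        got = draw_mu(state, np.random.default_rng(0), mu_prior=(-1.0, 1e-18))
        assert got == pytest.approx(-1.0, abs=1e-6)


class TestDrawSigma2E:
    def test_hand_scale_and_df(self):
        # nu_e=4, S2_e=1, n=2, e'e=6 -> scale 5/3, df 6
        hyper = Hyperparameters(pi=0.5, nu_e=4, s2_e=1)
        e = math.sqrt(3.0)
        state = bare_state([e, e])
        got = draw_sigma2_e(state, hyper, np.random.default_rng(77))
        oracle = draw_scaled_inv_chi2(6, 5.0 / 3.0, np.random.default_rng(77))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_zero_residual(self):
        hyper = Hyperparameters(pi=0.5, nu_e=4, s2_e=2)
        state = bare_state([0.0, 0.0, 0.0])
        got = draw_sigma2_e(state, hyper, np.random.default_rng(1))
        oracle = draw_scaled_inv_chi2(7, 4 * 2 / 7, np.random.default_rng(1))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_empty_data_recovers_prior(self):
        hyper = Hyperparameters(pi=0.5, nu_e=5, s2_e=1.3)
        state = bare_state(np.empty(0))
        got = draw_sigma2_e(state, hyper, np.random.default_rng(3))
        oracle = draw_scaled_inv_chi2(5, 1.3, np.random.default_rng(3))
        assert got == pytest.approx(oracle, rel=1e-12)


class TestDrawSigma2J:
    hyper = Hyperparameters(pi=0.5, nu_beta=4, s2_beta=1)

    def test_beta_zero_any_mode(self):
        for mode in ("single_site", "joint"):
            got = draw_sigma2_j(0.0, 1, self.hyper, mode, np.random.default_rng(9))
            oracle = draw_scaled_inv_chi2(5, 4 / 5, np.random.default_rng(9))
            assert got == pytest.approx(oracle, rel=1e-12)

    def test_hand_scale(self):
        # nu=4, S2=1, beta=2 -> scale (4+4)/5 = 1.6, df 5
        got = draw_sigma2_j(2.0, 1, self.hyper, "single_site", np.random.default_rng(4))
        oracle = draw_scaled_inv_chi2(5, 1.6, np.random.default_rng(4))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_single_site_ignores_delta(self):
        a = draw_sigma2_j(2.0, 0, self.hyper, "single_site", np.random.default_rng(4))
        b = draw_sigma2_j(2.0, 1, self.hyper, "single_site", np.random.default_rng(4))
        assert a == b

    def test_pseudo_excluded_draws_prior(self):
        got = draw_sigma2_j(2.0, 0, self.hyper, "pseudo", np.random.default_rng(6))
        oracle = draw_scaled_inv_chi2(4, 1, np.random.default_rng(6))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            draw_sigma2_j(0.0, 1, self.hyper, "bogus", np.random.default_rng(0))


class TestDrawBetaGivenDelta:
    def test_included_parameters(self):
        # rhs=2, xtx=2, s2e=1, s2j=1 -> c=3, N(2/3, 1/3)
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1)
        got = draw_beta_given_delta(ls, 1, np.random.default_rng(8))
        z = np.random.default_rng(8).standard_normal()
        assert got == pytest.approx(2 / 3 + math.sqrt(1 / 3) * z, rel=1e-12)

    def test_excluded_is_prior_independent_of_rhs(self):
        ls1 = LocusSufficientStats(rhs=100, xtx=2, sigma2_j=4, sigma2_e=1)
        ls2 = LocusSufficientStats(rhs=-3, xtx=2, sigma2_j=4, sigma2_e=1)
        a = draw_beta_given_delta(ls1, 0, np.random.default_rng(2))
        b = draw_beta_given_delta(ls2, 0, np.random.default_rng(2))
        assert a == b == pytest.approx(2.0 * np.random.default_rng(2).standard_normal())

    def test_least_squares_limit(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1e14, sigma2_e=1)
        got = draw_beta_given_delta(ls, 1, np.random.default_rng(3))
        z = np.random.default_rng(3).standard_normal()
        assert got == pytest.approx(1.0 + math.sqrt(0.5) * z, rel=1e-6)

    def test_monte_carlo_moments(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1)
        rng = np.random.default_rng(10)
        draws = np.array([draw_beta_given_delta(ls, 1, rng) for _ in range(50_000)])
        assert abs(draws.mean() - 2 / 3) < 3 * math.sqrt((1 / 3) / 50_000)
        assert draws.var(ddof=1) == pytest.approx(1 / 3, rel=0.05)


class TestProbDelta1SingleSite:
    def test_pi_boundaries_exact(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=1, pi=0.0)
        assert prob_delta1_single_site(ls) == 1.0
        ls.pi = 1.0
        assert prob_delta1_single_site(ls) == 0.0

    def test_beta_zero_gives_one_minus_pi(self):
        ls = LocusSufficientStats(rhs=5, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=0.0, pi=0.3)
        assert prob_delta1_single_site(ls) == pytest.approx(0.7, rel=1e-12)

    def test_hand_example_against_brute_force(self):
        # w = [1, -1], X = [1, -1]: rhs = 2, xtx = 2
        w, x = np.array([1.0, -1.0]), np.array([1.0, -1.0])
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=1, pi=0.5)
        got = prob_delta1_single_site(ls)
        assert got == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-12)
        assert got == pytest.approx(brute_force_p1_single_site(w, x, 1.0, 1.0, 0.5), abs=1e-10)

    def test_random_instances_against_brute_force(self):
        rng = np.random.default_rng(2023)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            x = rng.normal(size=n)
            w = rng.normal(size=n)
            beta = rng.normal()
            s2e = float(rng.uniform(0.2, 3.0))
            pi = float(rng.uniform(0.05, 0.95))
            ls = LocusSufficientStats(
                rhs=float(x @ w), xtx=float(x @ x), sigma2_j=1.0,
                sigma2_e=s2e, beta_j=beta, pi=pi,
            )
            assert prob_delta1_single_site(ls) == pytest.approx(
                brute_force_p1_single_site(w, x, beta, s2e, pi), abs=1e-10
            )

    def test_monotone_in_pi(self):
        probs = []
        for pi in np.linspace(0, 1, 21):
            ls = LocusSufficientStats(rhs=1.5, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=0.8, pi=pi)
            probs.append(prob_delta1_single_site(ls))
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert all(0.0 <= p <= 1.0 for p in probs)


class TestLogMarglikUnivariate:
    def test_zero_sigma2j_collapses(self):
        for rhs in (-3.0, 0.0, 2.5):
            assert log_marglik_univariate(rhs, 2.0, 0.0, 1.5, 1) == pytest.approx(
                log_marglik_univariate(rhs, 2.0, 0.0, 1.5, 0)
            )

    def test_density_values(self):
        # rhs=2, xtx=2, s2j=1, s2e=1: m1 = N(2; 0, 6), m0 = N(2; 0, 2)
        m1 = math.exp(log_marglik_univariate(2, 2, 1, 1, 1))
        m0 = math.exp(log_marglik_univariate(2, 2, 1, 1, 0))
        assert m1 == pytest.approx(stats.norm.pdf(2, scale=math.sqrt(6)), rel=1e-10)
        assert m0 == pytest.approx(stats.norm.pdf(2, scale=math.sqrt(2)), rel=1e-10)
        assert m1 == pytest.approx(0.11670, abs=5e-6)
        assert m0 == pytest.approx(0.10378, abs=5e-6)

    def test_m1_matches_numeric_integration(self):
        m1 = math.exp(log_marglik_univariate(2, 2, 1, 1, 1))
        assert m1 == pytest.approx(integrated_m1(2, 2, 1, 1), rel=1e-8)

    def test_closed_form_at_mode(self):
        xtx, s2j, s2e = 2.0, 1.5, 0.7
        gap = log_marglik_univariate(0, xtx, s2j, s2e, 0) - log_marglik_univariate(0, xtx, s2j, s2e, 1)
        assert gap == pytest.approx(0.5 * math.log((xtx * s2j + s2e) / s2e), rel=1e-12)
        assert gap > 0

    def test_nonpositive_xtx_rejected(self):
        with pytest.raises(ValueError, match="xtx"):
            log_marglik_univariate(1.0, 0.0, 1.0, 1.0, 1)


class TestProbDelta1Joint:
    def test_pi_zero(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, pi=0.0)
        assert prob_delta1_joint(ls) == 1.0

    def test_sigma2j_zero_gives_one_minus_pi(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=0.0, sigma2_e=1, pi=0.3)
        assert prob_delta1_joint(ls) == pytest.approx(0.7, rel=1e-12)

    def test_hand_example(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, pi=0.5)
        m1, m0 = 0.1167033, 0.1037769
        assert prob_delta1_joint(ls) == pytest.approx(m1 / (m1 + m0), abs=1e-5)
        assert prob_delta1_joint(ls) == pytest.approx(0.5293, abs=1e-4)

    def test_independent_of_current_beta(self):
        a = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=0.0, pi=0.4)
        b = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=9.9, pi=0.4)
        assert prob_delta1_joint(a) == prob_delta1_joint(b)

    def test_monotone_in_pi(self):
        probs = [
            prob_delta1_joint(
                LocusSufficientStats(rhs=1.5, xtx=2, sigma2_j=1, sigma2_e=1, pi=pi)
            )
            for pi in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestPseudoPrior:
    def test_hand_params(self):
        # rhs=3, xtx=2, lambda~=1 (s2e~=1, s2j~=1) -> mean 1, variance 1/3
        hyper = Hyperparameters(pi=0.5, pseudo_sigma2_e=1.0, pseudo_sigma2_j=1.0)
        mean, var = pseudo_prior_params(3.0, 2.0, hyper)
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(1 / 3)

    def test_data_dominated_limit(self):
        hyper = Hyperparameters(pi=0.5, pseudo_sigma2_e=1.0, pseudo_sigma2_j=1.0)
        xtx = 1e12
        rhs = 3e12
        mean, var = pseudo_prior_params(rhs, xtx, hyper)
        assert mean == pytest.approx(rhs / xtx, rel=1e-9)
        assert var == pytest.approx(0.0, abs=1e-11)

    def test_current_variances_recover_full_conditional(self):
        # constants = current (s2e, s2j) make the pseudo prior equal the
        # delta=1 full conditional N(rhs/c, s2e/c)
        s2e, s2j, rhs, xtx = 1.3, 0.6, 2.2, 3.1
        hyper = Hyperparameters(pi=0.5, pseudo_sigma2_e=s2e, pseudo_sigma2_j=s2j)
        mean, var = pseudo_prior_params(rhs, xtx, hyper)
        c = xtx + s2e / s2j
        assert mean == pytest.approx(rhs / c, rel=1e-12)
        assert var == pytest.approx(s2e / c, rel=1e-12)

    def test_prob_pi_zero(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=1, pi=0.0)
        assert prob_delta1_pseudo(ls, (0.5, 0.3)) == 1.0

    def test_bad_pseudo_variance(self):
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=1, pi=0.5)
        with pytest.raises(ValueError, match="pseudo"):
            prob_delta1_pseudo(ls, (0.5, 0.0))

    def test_identity_with_joint_hand_example(self):
        # beta=1, rhs=2, xtx=2, s2e=s2j=1, pi=0.5, pseudo = exact full cond.
        ls = LocusSufficientStats(rhs=2, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=1, pi=0.5)
        p = prob_delta1_pseudo(ls, (2 / 3, 1 / 3))
        assert p == pytest.approx(prob_delta1_joint(ls), abs=1e-12)
        assert p == pytest.approx(0.5293, abs=1e-4)

    def test_identity_with_joint_randomized(self):
        rng = np.random.default_rng(314)
        for _ in range(200):
            ls = LocusSufficientStats(
                rhs=float(rng.normal(scale=3)),
                xtx=float(rng.uniform(0.1, 10)),
                sigma2_j=float(rng.uniform(0.1, 5)),
                sigma2_e=float(rng.uniform(0.1, 5)),
                beta_j=float(rng.normal(scale=2)),
                pi=float(rng.uniform(0.01, 0.99)),
            )
            c = ls.xtx + ls.sigma2_e / ls.sigma2_j
            pseudo = (ls.rhs / c, ls.sigma2_e / c)
            assert prob_delta1_pseudo(ls, pseudo) == pytest.approx(
                prob_delta1_joint(ls), abs=1e-12
            )

    def test_monotone_in_pi(self):
        probs = []
        for pi in np.linspace(0, 1, 21):
            ls = LocusSufficientStats(rhs=1.5, xtx=2, sigma2_j=1, sigma2_e=1, beta_j=0.8, pi=pi)
            probs.append(prob_delta1_pseudo(ls, (0.4, 0.5)))
        assert all(a >= b for a, b in zip(probs, probs[1:]))
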