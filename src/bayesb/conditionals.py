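"""Full-conditional draws and inclusion-probability formulas.

Stateless numerical core shared by all sampler kernels.  Every inclusion
probability is computed on the log scale from likelihood *ratios*: the
common factor exp(-w'w / 2 sigma2_e), which underflows for realistic n,
cancels algebraically and is never evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from bayesb.data_model import Hyperparameters, ModelState

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LocusSufficientStats:
    """Everything a locus update needs: the scalar statistic X_j'w ('rhs'),
    the cross-product X_j'X_j, the current variances, the current effect
    and the point-mass prior probability pi."""

    rhs: float
    xtx: float
    sigma2_j: float
    sigma2_e: float
    beta_j: float = 0.0
    pi: float = 0.0


def draw_scaled_inv_chi2(nu: float, s2: float, rng: np.random.Generator) -> float:
    """One draw of nu * S^2 / chi2_nu (mean nu*S^2/(nu-2) for nu > 2)."""
    if nu <= 0 or s2 <= 0:
        raise ValueError(f"need nu > 0 and s2 > 0, got nu={nu}, s2={s2}")
    return nu * s2 / rng.chisquare(nu)


def draw_mu(
    state: ModelState,
    rng: np.random.Generator,
    mu_prior: tuple[float, float] | None = None,
) -> float:
    """Gibbs draw of the overall mean; the residual is updated in place.

    With the model's flat prior the full conditional is
    N(mean(e_mu), sigma2_e / n) with e_mu = residual + 1*mu.  ``mu_prior``
    optionally supplies a proper N(m0, v0) prior (needed e.g. by
    prior-predictive correctness checks), in which case the conditional is
    the standard precision-weighted combination.
    """
    n = state.residual.shape[0]
    e_mu_sum = float(np.sum(state.residual)) + n * state.mu
    if mu_prior is None:
        if n == 0:
            raise ValueError("cannot draw mu with a flat prior and no data")
        mean = e_mu_sum / n
        var = state.sigma2_e / n
    else:
        m0, v0 = mu_prior
        if v0 <= 0:
            raise ValueError("mu prior variance must be positive")
        prec = n / state.sigma2_e + 1.0 / v0
        mean = (e_mu_sum / state.sigma2_e + m0 / v0) / prec
        var = 1.0 / prec
    new_mu = mean + math.sqrt(var) * rng.standard_normal()
    state.residual -= new_mu - state.mu
    state.mu = new_mu
    return new_mu


def draw_sigma2_e(state: ModelState, hyper: Hyperparameters, rng: np.random.Generator) -> float:
    """Gibbs draw of the residual variance: scaled inverse chi-square with
    scale (nu_e*S2_e + e'e)/(nu_e + n) and df nu_e + n."""
    n = state.residual.shape[0]
    ete = float(state.residual @ state.residual)
    df = hyper.nu_e + n
    scale = (hyper.nu_e * hyper.s2_e + ete) / df
    state.sigma2_e = draw_scaled_inv_chi2(df, scale, rng)
    return state.sigma2_e


def draw_sigma2_j(
    beta_j: float,
    delta_j: int,
    hyper: Hyperparameters,
    mode: str,
    rng: np.random.Generator,
) -> float:
    """Gibbs draw of a locus variance.

    ``single_site`` and ``joint`` modes always condition on the current
    beta_j (scale (nu*S2 + beta^2)/(nu+1), df nu+1).  ``pseudo`` mode uses
    that form only when the locus is in the model (delta_j = 1) and falls
    back to the prior otherwise, because under the pseudo prior beta_j
    carries no information about sigma2_j when delta_j = 0.
    """
    if mode not in ("single_site", "joint", "pseudo"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pseudo" and delta_j == 0:
        return draw_scaled_inv_chi2(hyper.nu_beta, hyper.s2_beta, rng)
    df = hyper.nu_beta + 1.0
    scale = (hyper.nu_beta * hyper.s2_beta + beta_j * beta_j) / df
    return draw_scaled_inv_chi2(df, scale, rng)


def draw_beta_given_delta(
    ls: LocusSufficientStats, delta_j: int, rng: np.random.Generator
) -> float:
    """delta_j = 1: N(rhs/c_j, sigma2_e/c_j) with c_j = xtx + sigma2_e/sigma2_j;
    delta_j = 0: the N(0, sigma2_j) prior."""
    if ls.sigma2_j <= 0 or ls.sigma2_e <= 0:
        raise ValueError("variances must be positive")
    if delta_j:
        c = ls.xtx + ls.sigma2_e / ls.sigma2_j
        return ls.rhs / c + math.sqrt(ls.sigma2_e / c) * rng.standard_normal()
    return math.sqrt(ls.sigma2_j) * rng.standard_normal()


def _p1_from_logratio(log_r: float, pi: float) -> float:
    """1 / (1 + (pi/(1-pi)) * exp(-log_r)), stable for large |log_r|."""
    if pi >= 1.0:
        return 0.0
    if pi <= 0.0:
        return 1.0
    # log odds of inclusion
    t = log_r + math.log1p(-pi) - math.log(pi)
    if t >= 0:
        return 1.0 / (1.0 + math.exp(-t))
    e = math.exp(t)
    return e / (1.0 + e)


def prob_delta1_single_site(ls: LocusSufficientStats) -> float:
    """Pr(delta_j = 1 | ELSE) conditioning on the current beta_j.

    The likelihood ratio d_j / exp(-w'w/2 sigma2_e) reduces to
    exp((beta*rhs - beta^2*xtx/2) / sigma2_e).
    """
    r = (ls.beta_j * ls.rhs - 0.5 * ls.beta_j * ls.beta_j * ls.xtx) / ls.sigma2_e
    return _p1_from_logratio(r, ls.pi)


def log_marglik_univariate(
    rhs: float, xtx: float, sigma2_j: float, sigma2_e: float, delta: int
) -> float:
    """log density of the scalar statistic X_j'w under delta_j = delta.

    delta = 1: N(0, xtx^2*sigma2_j + xtx*sigma2_e); delta = 0: N(0, xtx*sigma2_e).
    """
    if xtx <= 0:
        raise ValueError("xtx must be positive (monomorphic markers excluded upstream)")
    var = xtx * sigma2_e + (xtx * xtx * sigma2_j if delta else 0.0)
    return -0.5 * (_LOG_2PI + math.log(var) + rhs * rhs / var)


def prob_delta1_joint(ls: LocusSufficientStats) -> float:
    """Marginal (beta_j integrated out) Pr(delta_j = 1 | ELSE) from the
    univariate m1/m0 densities of X_j'w."""
    lm1 = log_marglik_univariate(ls.rhs, ls.xtx, ls.sigma2_j, ls.sigma2_e, 1)
    lm0 = log_marglik_univariate(ls.rhs, ls.xtx, ls.sigma2_j, ls.sigma2_e, 0)
    return _p1_from_logratio(lm1 - lm0, ls.pi)


def pseudo_prior_params(
    rhs: float, xtx: float, hyper: Hyperparameters
) -> tuple[float, float]:
    """Normal pseudo-prior parameters for beta_j while delta_j = 0:
    mean rhs/(xtx + lambda~), variance sigma2_e~/(xtx + lambda~), with the
    tilde constants fixed across the run (defaults: prior means)."""
    s2e_t, s2j_t = hyper.resolve_pseudo_constants()
    lam = s2e_t / s2j_t
    denom = xtx + lam
    return rhs / denom, s2e_t / denom


def _log_normal_pdf(x: float, mean: float, var: float) -> float:
    d = x - mean
    return -0.5 * (_LOG_2PI + math.log(var) + d * d / var)


def prob_delta1_pseudo(
    ls: LocusSufficientStats, pseudo: tuple[float, float]
) -> float:
    """Pr(delta_j = 1 | ELSE) under the pseudo-prior construction: the
    single-site log ratio plus log N(beta; 0, sigma2_j) - log N(beta; pseudo)."""
    p_mean, p_var = pseudo
    if p_var <= 0:
        raise ValueError("pseudo-prior variance must be positive")
    r = (ls.beta_j * ls.rhs - 0.5 * ls.beta_j * ls.beta_j * ls.xtx) / ls.sigma2_e
    r += _log_normal_pdf(ls.beta_j, 0.0, ls.sigma2_j)
    r -= _log_normal_pdf(ls.beta_j, p_mean, p_var)
    return _p1_from_logratio(r, ls.pi)
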