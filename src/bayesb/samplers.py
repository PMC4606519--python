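"""The five locus-update kernels and the chain runner.

Every kernel updates one locus of the shared :class:`ModelState` in place
(delta_j, beta_j, sigma2_j and the residual) and all of them leave the same
posterior invariant; they differ only in how the (delta_j, beta_j) pair is
traversed:

* ``single_site_gibbs``  - delta_j | beta_j, then beta_j | delta_j;
* ``joint_gibbs``        - delta_j marginalized over beta_j, then beta_j;
* ``pseudo_gibbs``       - single-site form with a pseudo prior on beta_j
                           while delta_j = 0;
* ``mh``                 - Metropolis-Hastings on sigma2_j with the mixture
                           prior as proposal (default 100 cycles/locus);
* ``efficient_mh``       - MH with a half-and-half point-mass proposal
                           (default 5 cycles/locus).

The MH kernels carry the original (sigma2_j, alpha_j) parameterization:
delta_j = 0 encodes the sigma2_j = 0 point-mass state (the stored sigma2_j
entry keeps its last positive value so state invariants hold).
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np

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
from bayesb.data_model import (
    GenotypeMatrix,
    Hyperparameters,
    ModelState,
    Phenotypes,
    PosteriorDraws,
    rebuild_residual,
    update_residual,
)

logger = logging.getLogger(__name__)

SAMPLER_KINDS = ("mh", "efficient_mh", "single_site_gibbs", "joint_gibbs", "pseudo_gibbs")

#: how often the residual is recomputed from scratch to cap drift
REBUILD_EVERY = 1000


@dataclass
class SamplerSpec:
    """Which kernel to run and for how long."""

    kind: str
    chain_length: int = 50_000
    burn_in: int | None = None  # default: 10% of chain_length
    thin: int = 1
    seed: int | None = None
    mh_cycles: int | None = None  # default 100 for mh, 5 for efficient_mh
    scan: str = "systematic"  # or "random"

    def __post_init__(self) -> None:
        if self.kind not in SAMPLER_KINDS:
            raise ValueError(
                f"unknown sampler kind {self.kind!r}; choose from {SAMPLER_KINDS}"
            )
        if self.burn_in is None:
            self.burn_in = self.chain_length // 10
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < chain_length ({self.chain_length})"
            )
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.mh_cycles is None:
            self.mh_cycles = 100 if self.kind == "mh" else 5
        if self.mh_cycles < 1:
            raise ValueError("mh_cycles must be >= 1")
        if self.scan not in ("systematic", "random"):
            raise ValueError("scan must be 'systematic' or 'random'")


# ---------------------------------------------------------------------------
# Gibbs kernels


def _locus_stats(state: ModelState, G: GenotypeMatrix, j: int, pi: float) -> LocusSufficientStats:
    rhs = float(G.values[:, j] @ state.residual)
    if state.delta[j]:
        rhs += float(G.xtx[j]) * float(state.beta[j])
    return LocusSufficientStats(
        rhs=rhs,
        xtx=float(G.xtx[j]),
        sigma2_j=float(state.sigma2_j[j]),
        sigma2_e=state.sigma2_e,
        beta_j=float(state.beta[j]),
        pi=pi,
    )


def update_locus_single_site(
    state: ModelState, G: GenotypeMatrix, j: int, hyper: Hyperparameters, rng: np.random.Generator
) -> ModelState:
    """Full-conditional sweep at locus j: delta (given current beta), beta,
    then the locus variance."""
    ls = _locus_stats(state, G, j, hyper.pi)
    alpha_old = ls.beta_j * state.delta[j]
    new_delta = 1 if rng.random() < prob_delta1_single_site(ls) else 0
    new_beta = draw_beta_given_delta(ls, new_delta, rng)
    state.delta[j] = new_delta
    state.beta[j] = new_beta
    state.sigma2_j[j] = draw_sigma2_j(new_beta, new_delta, hyper, "single_site", rng)
    return update_residual(state, G, j, alpha_old, new_beta * new_delta)


def update_locus_joint(
    state: ModelState, G: GenotypeMatrix, j: int, hyper: Hyperparameters, rng: np.random.Generator
) -> ModelState:
    """Blocked update: delta from its marginal full conditional (beta
    integrated out), then beta | delta, then the locus variance."""
    ls = _locus_stats(state, G, j, hyper.pi)
    alpha_old = ls.beta_j * state.delta[j]
    new_delta = 1 if rng.random() < prob_delta1_joint(ls) else 0
    new_beta = draw_beta_given_delta(ls, new_delta, rng)
    state.delta[j] = new_delta
    state.beta[j] = new_beta
    state.sigma2_j[j] = draw_sigma2_j(new_beta, new_delta, hyper, "joint", rng)
    return update_residual(state, G, j, alpha_old, new_beta * new_delta)


def update_locus_pseudo(
    state: ModelState,
    G: GenotypeMatrix,
    j: int,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    pseudo_constants: tuple[float, float] | None = None,
) -> ModelState:
    """Single-site sweep with a pseudo prior on beta_j while delta_j = 0.

    ``pseudo_constants`` may override the (sigma2_e~, sigma2_j~) pair; by
    default the run-level constants from ``hyper`` apply.
    """
    ls = _locus_stats(state, G, j, hyper.pi)
    alpha_old = ls.beta_j * state.delta[j]
    if pseudo_constants is None:
        s2e_t, s2j_t = hyper.resolve_pseudo_constants()
    else:
        s2e_t, s2j_t = pseudo_constants
    denom = ls.xtx + s2e_t / s2j_t
    pseudo = (ls.rhs / denom, s2e_t / denom)
    new_delta = 1 if rng.random() < prob_delta1_pseudo(ls, pseudo) else 0
    if new_delta:
        new_beta = draw_beta_given_delta(ls, 1, rng)
    else:
        new_beta = pseudo[0] + math.sqrt(pseudo[1]) * rng.standard_normal()
    state.delta[j] = new_delta
    state.beta[j] = new_beta
    state.sigma2_j[j] = draw_sigma2_j(new_beta, new_delta, hyper, "pseudo", rng)
    return update_residual(state, G, j, alpha_old, new_beta * new_delta)


# ---------------------------------------------------------------------------
# Metropolis-Hastings kernels

_LOG_2PI = math.log(2.0 * math.pi)


def _mh_core(
    state: ModelState,
    G: GenotypeMatrix,
    j: int,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    cycles: int,
    half_point_mass: bool,
) -> ModelState:
    """Shared MH machinery: random walk over sigma2_j in {0} U (0, inf),
    then a final beta draw at the accepted variance."""
    xtx = float(G.xtx[j])
    alpha_old = float(state.beta[j]) * state.delta[j]
    rhs = float(G.values[:, j] @ state.residual) + xtx * alpha_old
    sigma2_e = state.sigma2_e
    pi = hyper.pi

    def log_m(s: float) -> float:
        var = xtx * sigma2_e + xtx * xtx * s
        return -0.5 * (_LOG_2PI + math.log(var) + rhs * rhs / var)

    # point-mass log weights of target prior and proposal
    lp0 = math.log(pi) if pi > 0 else -math.inf
    lp1 = math.log1p(-pi) if pi < 1 else -math.inf
    if half_point_mass:
        # proposal puts 0.5 on the point mass; the log(0.5) terms cancel in
        # the ratio, so only the target's point-mass weights remain
        lw0, lw1 = lp0, lp1
        zero_prob = 0.5
    else:
        # proposal = prior, everything cancels
        lw0 = lw1 = 0.0
        zero_prob = pi

    point = rng.random(cycles) < zero_prob
    props = np.where(
        point, 0.0, hyper.nu_beta * hyper.s2_beta / rng.chisquare(hyper.nu_beta, cycles)
    )
    log_u = np.log(rng.random(cycles))

    s_cur = float(state.sigma2_j[j]) if state.delta[j] else 0.0
    logw_cur = (log_m(s_cur) + lw1) if s_cur > 0 else (log_m(0.0) + lw0)
    for i in range(cycles):
        s_prop = props[i]
        logw_prop = (log_m(s_prop) + lw1) if s_prop > 0 else (log_m(0.0) + lw0)
        if log_u[i] < logw_prop - logw_cur:
            s_cur = s_prop
            logw_cur = logw_prop

    if s_cur > 0:
        state.delta[j] = 1
        state.sigma2_j[j] = s_cur
        c = xtx + sigma2_e / s_cur
        new_beta = rhs / c + math.sqrt(sigma2_e / c) * rng.standard_normal()
        state.beta[j] = new_beta
        alpha_new = new_beta
    else:
        state.delta[j] = 0
        state.beta[j] = 0.0
        alpha_new = 0.0  # sigma2_j entry keeps its last positive value
    return update_residual(state, G, j, alpha_old, alpha_new)


def update_locus_mh(
    state: ModelState,
    G: GenotypeMatrix,
    j: int,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    cycles: int = 100,
) -> ModelState:
    """MH over sigma2_j using the mixture prior itself as the proposal;
    acceptance reduces to the marginal-likelihood ratio m(s*)/m(s)."""
    return _mh_core(state, G, j, hyper, rng, cycles, half_point_mass=False)


def update_locus_mh_efficient(
    state: ModelState,
    G: GenotypeMatrix,
    j: int,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    cycles: int = 5,
) -> ModelState:
    """MH whose proposal puts probability 0.5 on sigma2_j = 0 (and the prior
    shape otherwise); the acceptance ratio keeps the target's pi/(1-pi)
    point-mass weights."""
    return _mh_core(state, G, j, hyper, rng, cycles, half_point_mass=True)


# ---------------------------------------------------------------------------
# chain runner

LOCUS_UPDATERS = {
    "single_site_gibbs": update_locus_single_site,
    "joint_gibbs": update_locus_joint,
    "pseudo_gibbs": update_locus_pseudo,
    "mh": update_locus_mh,
    "efficient_mh": update_locus_mh_efficient,
}


def make_locus_updater(kind: str, hyper: Hyperparameters, spec: SamplerSpec):
    """Bind kernel options so the returned callable has the uniform
    signature (state, G, j, rng)."""
    if kind == "pseudo_gibbs":
        constants = hyper.resolve_pseudo_constants()

        def step(state, G, j, rng):
            return update_locus_pseudo(state, G, j, hyper, rng, constants)

    elif kind in ("mh", "efficient_mh"):
        fn = LOCUS_UPDATERS[kind]
        cycles = spec.mh_cycles

        def step(state, G, j, rng):
            return fn(state, G, j, hyper, rng, cycles)

    else:
        fn = LOCUS_UPDATERS[kind]

        def step(state, G, j, rng):
            return fn(state, G, j, hyper, rng)

    return step


def _update_pinned(state: ModelState, j: int, hyper: Hyperparameters, rng: np.random.Generator) -> None:
    """Monomorphic marker: delta pinned at 0, beta and sigma2_j refreshed
    from their priors so the stored chain remains proper."""
    state.delta[j] = 0
    state.sigma2_j[j] = draw_scaled_inv_chi2(hyper.nu_beta, hyper.s2_beta, rng)
    state.beta[j] = math.sqrt(state.sigma2_j[j]) * rng.standard_normal()


def run_chain(
    G: GenotypeMatrix,
    y: Phenotypes,
    hyper: Hyperparameters,
    spec: SamplerSpec,
    mu_prior: tuple[float, float] | None = None,
) -> PosteriorDraws:
    """Run one MCMC chain and return stored post-burn-in draws.

    Each iteration sweeps mu, all loci (with the kernel selected by
    ``spec.kind``), and sigma2_e.  Identical inputs, spec and seed produce
    bit-identical output.
    """
    if y.n != G.n_individuals:
        raise ValueError(
            f"{y.n} phenotypes but {G.n_individuals} genotyped individuals"
        )
    rng = np.random.default_rng(spec.seed)
    state = ModelState.initial(G, y, hyper)
    k = G.n_markers
    pinned = np.flatnonzero(G.monomorphic)
    pinned_set = set(int(p) for p in pinned)
    active = np.array([j for j in range(k) if j not in pinned_set], dtype=np.intp)
    step = make_locus_updater(spec.kind, hyper, spec)

    n_stored = (spec.chain_length - spec.burn_in) // spec.thin
    mu_draws = np.empty(n_stored)
    s2e_draws = np.empty(n_stored)
    alpha_draws = np.empty((n_stored, k))
    delta_sum = np.zeros(k)
    stored_iters = np.empty(n_stored, dtype=np.int64)

    t0 = time.perf_counter()
    s = 0
    for it in range(1, spec.chain_length + 1):
        draw_mu(state, rng, mu_prior)
        order = active if spec.scan == "systematic" else rng.permutation(active)
        for j in order:
            step(state, G, int(j), rng)
        for j in pinned:
            _update_pinned(state, int(j), hyper, rng)
        draw_sigma2_e(state, hyper, rng)
        if it % REBUILD_EVERY == 0:
            rebuild_residual(state, G, y)
        if it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            mu_draws[s] = state.mu
            s2e_draws[s] = state.sigma2_e
            alpha_draws[s, :] = state.beta * state.delta
            delta_sum += state.delta
            stored_iters[s] = it
            s += 1
    wall = time.perf_counter() - t0
    rebuild_residual(state, G, y)

    logger.info(
        "%s: %d iterations (%d stored) in %.2fs", spec.kind, spec.chain_length, s, wall
    )
    return PosteriorDraws(
        mu=mu_draws[:s],
        sigma2_e=s2e_draws[:s],
        alpha=alpha_draws[:s],
        delta_freq=delta_sum / max(s, 1),
        iterations=stored_iters[:s],
        marker_ids=list(G.marker_ids),
        sampler=spec.kind,
        wall_seconds=wall,
        n_iter=spec.chain_length,
        burn_in=spec.burn_in,
        thin=spec.thin,
        seed=spec.seed,
    )
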