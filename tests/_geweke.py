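"""Geweke joint-distribution test harness for MCMC kernel correctness.

Two ways of sampling the joint distribution of (parameters, data) must agree:

* marginal-conditional: draw parameters from the prior (i.i.d.);
* successive-conditional: alternate one sweep of the transition kernel under
  test with regeneration of the data given the current parameters.

If the kernel has the correct invariant distribution, any function of the
parameters has the same distribution under both schemes.  We compare the
first two moments of mu, sigma2_e and the number of included markers via
z-scores (i.i.d. standard errors on the prior side, ESS-corrected standard
errors on the chain side).

The model's flat prior on mu cannot be simulated from, so the harness runs
with a proper N(0, v0) prior on mu, which every kernel supports through the
``mu_prior`` argument of the mu draw.
"""

from __future__ import annotations

import numpy as np

from bayesb.conditionals import draw_mu, draw_scaled_inv_chi2, draw_sigma2_e
from bayesb.data_model import (
    GenotypeMatrix,
    Hyperparameters,
    ModelState,
    center_genotypes,
)
from bayesb.diagnostics import effective_sample_size
from bayesb.samplers import SamplerSpec, make_locus_updater

MU_PRIOR = (0.0, 1.0)

#: nu > 4 so the compared second moments of the variances exist
GEWEKE_HYPER = Hyperparameters(pi=0.5, nu_beta=10.0, s2_beta=0.5, nu_e=10.0, s2_e=0.5)


def _prior_state(G: GenotypeMatrix, hyper: Hyperparameters, rng) -> ModelState:
    k = G.n_markers
    sigma2_j = np.array([draw_scaled_inv_chi2(hyper.nu_beta, hyper.s2_beta, rng) for _ in range(k)])
    beta = rng.standard_normal(k) * np.sqrt(sigma2_j)
    delta = (rng.random(k) < 1.0 - hyper.pi).astype(np.int8)
    mu = MU_PRIOR[0] + np.sqrt(MU_PRIOR[1]) * rng.standard_normal()
    sigma2_e = draw_scaled_inv_chi2(hyper.nu_e, hyper.s2_e, rng)
    return ModelState(
        mu=mu, beta=beta, delta=delta, sigma2_j=sigma2_j,
        sigma2_e=sigma2_e, residual=np.zeros(G.n_individuals),
    )


def _regenerate_data(state: ModelState, G: GenotypeMatrix, rng) -> None:
    """y ~ N(1 mu + X (beta*delta), sigma2_e I); only the residual matters."""
    n = G.n_individuals
    state.residual = rng.standard_normal(n) * np.sqrt(state.sigma2_e)


def _stats(state: ModelState) -> tuple[float, float, float]:
    return state.mu, state.sigma2_e, float(np.sum(state.delta))


def marginal_conditional(G, hyper, n_samples, rng) -> np.ndarray:
    out = np.empty((n_samples, 3))
    for i in range(n_samples):
        out[i] = _stats(_prior_state(G, hyper, rng))
    return out


def successive_conditional(kind, G, hyper, n_samples, rng, mh_cycles=None) -> np.ndarray:
    spec = SamplerSpec(kind=kind, chain_length=10, mh_cycles=mh_cycles)
    step = make_locus_updater(kind, hyper, spec)
    state = _prior_state(G, hyper, rng)
    _regenerate_data(state, G, rng)
    if kind in ("mh", "efficient_mh"):
        # point-mass parameterization: beta only defined while delta = 1
        state.beta[state.delta == 0] = 0.0
    out = np.empty((n_samples, 3))
    for i in range(n_samples):
        draw_mu(state, rng, MU_PRIOR)
        for j in range(G.n_markers):
            step(state, G, j, rng)
        draw_sigma2_e(state, hyper, rng)
        _regenerate_data(state, G, rng)
        out[i] = _stats(state)
    return out


def geweke_zscores(kind: str, n: int = 8, k: int = 2, n_samples: int = 50_000,
                   seed: int = 0, hyper: Hyperparameters = GEWEKE_HYPER) -> dict[str, float]:
    """Max-|z| comparison of first and second moments of (mu, sigma2_e,
    sum delta) between the two simulation schemes."""
    rng = np.random.default_rng(seed)
    raw = rng.binomial(2, 0.4, size=(n, k)).astype(float)
    G = center_genotypes(raw)
    assert not G.monomorphic.any(), "fixture genotypes must be polymorphic"

    prior = marginal_conditional(G, hyper, n_samples, rng)
    chain = successive_conditional(kind, G, hyper, n_samples, rng)

    names = ("mu", "sigma2_e", "sum_delta")
    z = {}
    for c, name in enumerate(names):
        for power, tag in ((1, ""), (2, "^2")):
            a = prior[:, c] ** power
            b = chain[:, c] ** power
            se_a = np.std(a, ddof=1) / np.sqrt(len(a))
            ess_b = effective_sample_size(b)
            se_b = np.std(b, ddof=1) / np.sqrt(ess_b)
            z[name + tag] = float(
                (np.mean(a) - np.mean(b)) / np.hypot(se_a, se_b)
            )
    return z
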