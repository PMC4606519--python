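"""Shared fixtures.

The cross-sampler benchmark (one simulated dataset, all five kernels at
20,000 iterations) is expensive, so it is built once per session and only
when an acceptance test requests it.
"""

import numpy as np
import pytest

from bayesb.data_model import Hyperparameters
from bayesb.samplers import SAMPLER_KINDS, SamplerSpec, run_chain
from bayesb.simulate import SimConfig, simulate_dataset

BENCHMARK_SEED = 20150
BENCHMARK_CFG = SimConfig(
    n_individuals=200,
    n_markers=50,
    pi_true=0.9,
    heritability=0.25,
    train_fraction=0.8,
    seed=BENCHMARK_SEED,
)
BENCHMARK_ITER = 20_000
BENCHMARK_BURNIN = 2_000


@pytest.fixture(scope="session")
def benchmark_data():
    return simulate_dataset(BENCHMARK_CFG)


@pytest.fixture(scope="session")
def benchmark_hyper(benchmark_data):
    ds = benchmark_data
    return Hyperparameters.default(ds.G_train, ds.train.y.y, pi=0.9)


@pytest.fixture(scope="session")
def benchmark_chains(benchmark_data, benchmark_hyper):
    """All five kernels on the same simulated dataset and hyperparameters."""
    ds = benchmark_data
    chains = {}
    for i, kind in enumerate(SAMPLER_KINDS):
        spec = SamplerSpec(
            kind=kind,
            chain_length=BENCHMARK_ITER,
            burn_in=BENCHMARK_BURNIN,
            seed=BENCHMARK_SEED + 1 + i,
        )
        chains[kind] = run_chain(ds.G_train, ds.train.y, benchmark_hyper, spec)
    return chains
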