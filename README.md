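# bayesb

Bayesian whole-genome regression (BayesB) with five interchangeable MCMC
kernels, a synthetic-data simulator, and chain diagnostics.

The model is a spike-and-slab multiple regression of a phenotype on centered
marker covariates:

    y_i = mu + sum_j X_ij * beta_j * delta_j + e_i

where `delta_j` is 1 with probability `1 - pi`, `beta_j | sigma2_j ~ N(0,
sigma2_j)`, and `sigma2_j` and `sigma2_e` carry scaled inverse chi-square
priors.  Marginally each non-null effect follows a scaled-t distribution;
`pi = 0` reduces the model to BayesA.

Five locus-update kernels share this posterior and differ only in how the
`(delta_j, beta_j)` pair is traversed:

| kernel              | update of (delta_j, beta_j)                               |
| ------------------- | --------------------------------------------------------- |
| `single_site_gibbs` | delta given current beta, then beta given delta           |
| `joint_gibbs`       | delta with beta marginalized out, then beta given delta   |
| `pseudo_gibbs`      | single-site form with a pseudo prior on beta at delta = 0 |
| `mh`                | Metropolis-Hastings on sigma2_j, prior as proposal (100 cycles/locus) |
| `efficient_mh`      | MH with a 0.5 point-mass proposal (5 cycles/locus)        |

All inclusion probabilities are computed in log space from likelihood
ratios; the `exp(-w'w / 2 sigma2_e)` factor that underflows for realistic
sample sizes cancels algebraically and is never evaluated.

## Layout

- `bayesb.data_model` — genotype centering, model state, incremental
  residual bookkeeping, delimited-text readers/writers.
- `bayesb.conditionals` — stateless full-conditional draws and the three
  delta-probability formulas.
- `bayesb.samplers` — the five locus kernels and the chain runner.
- `bayesb.simulate` — synthetic genotypes (no LD), spike-and-slab effects,
  phenotypes with exact target heritability, train/test split.
- `bayesb.diagnostics` — effective sample size (initial monotone positive
  sequence estimator), posterior summaries, GEBV prediction accuracy,
  per-sampler efficiency reports.
- `bayesb.io_cli` — `bayesb` command line with `simulate` / `run` /
  `summarize` subcommands, TOML configuration, reproducibility manifests.

## Command line

```sh
# simulate a dataset (writes genotypes.tsv, phenotypes.tsv, truth.tsv, split.tsv)
bayesb simulate --out-dir sim --n 200 --k 50 --pi-true 0.9 --seed 1

# run one chain; sampler is one of mh, efficient-mh, single-site, joint, pseudo
bayesb run --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
    --out-dir run --sampler joint --chain-length 20000 --pi 0.9 --seed 1

# summarize a stored chain
bayesb summarize --chain run/chain_joint_gibbs.tsv \
    --manifest run/manifest_joint_gibbs.json --out-dir summary
```

Every `run` writes a JSON manifest (config, seed, input hashes, version);
re-running with the same inputs reproduces the chain file byte-for-byte.
Options may also come from a TOML config file (`--config`), with flags
taking precedence.

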