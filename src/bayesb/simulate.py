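"""Synthetic genotype/phenotype generator.

Markers are independent (no linkage disequilibrium): per marker an allele
frequency is drawn uniformly between the configured MAF bounds and genotype
codes are Binomial(2, p).  Effects follow the model's own prior — zero with
probability ``pi_true``, otherwise normal with a scaled inverse chi-square
variance (a scaled-t marginal).  Residual variance is set from the realized
genetic variance so the target heritability holds exactly per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from bayesb.data_model import GenotypeMatrix, Phenotypes, center_genotypes


@dataclass
class SimConfig:
    n_individuals: int = 200
    n_markers: int = 50
    maf_low: float = 0.05
    maf_high: float = 0.5
    pi_true: float = 0.9
    heritability: float = 0.25
    mu_true: float = 0.0
    train_fraction: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.pi_true <= 1.0:
            raise ValueError("pi_true must be in [0, 1]")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    alpha_true: np.ndarray
    sigma2_e_true: float
    sigma2_g_realized: float
    breeding_values: np.ndarray

    @property
    def heritability_realized(self) -> float:
        tot = self.sigma2_g_realized + self.sigma2_e_true
        return self.sigma2_g_realized / tot if tot > 0 else 0.0


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Raw 0/1/2 codes, one uniform allele frequency per marker, no LD."""
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_markers)
    return rng.binomial(2, p, size=(cfg.n_individuals, cfg.n_markers)).astype(np.float64)


def simulate_effects(
    cfg: SimConfig,
    rng: np.random.Generator,
    s2_beta: float = 1.0,
    nu_beta: float = 4.0,
) -> np.ndarray:
    """Spike-and-slab effects: zero w.p. pi_true, else N(0, s2) with
    s2 ~ nu*S2/chi2_nu (scaled-t marginal)."""
    k = cfg.n_markers
    nonzero = rng.random(k) >= cfg.pi_true
    alpha = np.zeros(k)
    idx = np.flatnonzero(nonzero)
    if idx.size:
        s2 = nu_beta * s2_beta / rng.chisquare(nu_beta, size=idx.size)
        alpha[idx] = rng.standard_normal(idx.size) * np.sqrt(s2)
    return alpha


def simulate_phenotypes(
    G_raw: np.ndarray,
    alpha_true: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[Phenotypes, SimTruth]:
    """y = mu + centered(G) @ alpha + e with e scaled to hit the target h2."""
    G_raw = np.asarray(G_raw, dtype=np.float64)
    if G_raw.shape[1] != alpha_true.shape[0]:
        raise ValueError("effect vector length does not match marker count")
    n = G_raw.shape[0]
    X = G_raw - G_raw.mean(axis=0)
    g = X @ alpha_true
    var_g = float(np.var(g, ddof=1)) if n > 1 else 0.0
    h2 = cfg.heritability
    if var_g <= 0 or h2 <= 0:
        sigma2_e = 1.0
        var_g = 0.0 if var_g <= 0 else var_g
        if h2 <= 0:
            g = np.zeros(n)
            var_g = 0.0
    else:
        sigma2_e = var_g * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=n)
    y = cfg.mu_true + g + e
    ids = [f"ind{i + 1}" for i in range(n)]
    truth = SimTruth(
        alpha_true=np.asarray(alpha_true, dtype=np.float64),
        sigma2_e_true=sigma2_e,
        sigma2_g_realized=var_g,
        breeding_values=g,
    )
    return Phenotypes(y=y, individual_ids=ids), truth


@dataclass
class SimSplit:
    """One side of a train/test partition (genotypes still raw codes)."""

    G_raw: np.ndarray
    y: Phenotypes
    breeding_values: np.ndarray
    indices: np.ndarray


def train_test_split(
    G_raw: np.ndarray,
    y: Phenotypes,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[SimSplit, SimSplit]:
    """Uniform random partition into train/test of sizes set by
    cfg.train_fraction; both sides keep aligned rows and truth."""
    n = G_raw.shape[0]
    n_train = int(round(cfg.train_fraction * n))
    if n_train <= 0 or n_train >= n:
        raise ValueError(
            f"train_fraction {cfg.train_fraction} gives a degenerate split "
            f"({n_train} of {n})"
        )
    perm = rng.permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    def take(idx: np.ndarray) -> SimSplit:
        ids = [y.individual_ids[i] for i in idx] if y.individual_ids else None
        return SimSplit(
            G_raw=G_raw[idx],
            y=Phenotypes(y=y.y[idx], individual_ids=ids),
            breeding_values=truth.breeding_values[idx],
            indices=idx,
        )

    return take(tr), take(te)


@dataclass
class SimDataset:
    """A complete simulated experiment: raw and centered genotypes,
    phenotypes, truth and the train/test partition."""

    cfg: SimConfig
    G_raw: np.ndarray
    y: Phenotypes
    truth: SimTruth
    train: SimSplit
    test: SimSplit
    G_train: GenotypeMatrix
    G_test: GenotypeMatrix  # centered with *training* column means


def simulate_dataset(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    s2_beta: float = 1.0,
    nu_beta: float = 4.0,
) -> SimDataset:
    """Generate genotypes, effects, phenotypes and a train/test split in one
    call; the test genotypes are centered with training means."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    G_raw = simulate_genotypes(cfg, rng)
    alpha = simulate_effects(cfg, rng, s2_beta=s2_beta, nu_beta=nu_beta)
    y, truth = simulate_phenotypes(G_raw, alpha, cfg, rng)
    train, test = train_test_split(G_raw, y, truth, cfg, rng)
    marker_ids = [f"m{j + 1}" for j in range(cfg.n_markers)]
    G_train = center_genotypes(
        train.G_raw, marker_ids=marker_ids, individual_ids=train.y.individual_ids
    )
    G_test = center_genotypes(
        test.G_raw,
        marker_ids=marker_ids,
        individual_ids=test.y.individual_ids,
        col_means=G_train.col_means,
    )
    return SimDataset(
        cfg=cfg, G_raw=G_raw, y=y, truth=truth,
        train=train, test=test, G_train=G_train, G_test=G_test,
    )
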