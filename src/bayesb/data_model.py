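"""Core data structures: centered genotypes, model state, residual bookkeeping.

All samplers share the same incremental-residual representation: the model
state carries ``e = y - 1*mu - sum_j X_j beta_j delta_j`` and every locus
update adjusts it in O(n) instead of recomputing the k-term sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns with X_j'X_j below this are treated as monomorphic
MONOMORPHIC_XTX = 1e-12


@dataclass
class GenotypeMatrix:
    """Centered marker covariate matrix with cached column cross-products."""

    values: np.ndarray  # n x k, float64, column-centered
    marker_ids: list[str]
    xtx: np.ndarray  # length k, X_j'X_j
    individual_ids: list[str] | None = None
    is_centered: bool = True
    col_means: np.ndarray | None = None  # means subtracted at centering time

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean mask of markers with (numerically) zero cross-product."""
        return self.xtx < MONOMORPHIC_XTX


@dataclass
class Phenotypes:
    """Trait values aligned to the genotype rows."""

    y: np.ndarray
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim != 1:
            raise ValueError("phenotype vector must be one-dimensional")
        if not np.all(np.isfinite(self.y)):
            bad = int(np.flatnonzero(~np.isfinite(self.y))[0])
            raise ValueError(f"non-finite phenotype at position {bad}")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class Hyperparameters:
    """Prior settings: pi, scaled inverse chi-square (nu, S^2) pairs,
    and the pseudo-prior constants used by the pseudo-prior kernel."""

    pi: float
    nu_beta: float = 4.0
    s2_beta: float = 1.0
    nu_e: float = 4.0
    s2_e: float = 1.0
    pseudo_sigma2_e: float | None = None
    pseudo_sigma2_j: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        for name in ("nu_beta", "s2_beta", "nu_e", "s2_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pseudo_sigma2_e", "pseudo_sigma2_j"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")

    @property
    def pseudo_lambda(self) -> float:
        s2e, s2j = self.resolve_pseudo_constants()
        return s2e / s2j

    def resolve_pseudo_constants(self) -> tuple[float, float]:
        """Pseudo-prior constants; default to the prior means of the residual
        and marker-effect variances, which requires nu > 2 on both."""
        s2e = self.pseudo_sigma2_e
        s2j = self.pseudo_sigma2_j
        if s2e is None:
            if self.nu_e <= 2:
                raise ValueError(
                    "pseudo_sigma2_e defaulting needs nu_e > 2 (prior mean "
                    "undefined); supply an explicit constant"
                )
            s2e = self.nu_e * self.s2_e / (self.nu_e - 2.0)
        if s2j is None:
            if self.nu_beta <= 2:
                raise ValueError(
                    "pseudo_sigma2_j defaulting needs nu_beta > 2 (prior mean "
                    "undefined); supply an explicit constant"
                )
            s2j = self.nu_beta * self.s2_beta / (self.nu_beta - 2.0)
        return float(s2e), float(s2j)

    @classmethod
    def default(
        cls,
        G: GenotypeMatrix,
        y: np.ndarray,
        pi: float,
        nu_beta: float = 4.0,
        nu_e: float = 4.0,
        h2_assumed: float = 0.5,
    ) -> "Hyperparameters":
        """Data-scaled defaults: S2_e = var(y)/2 and S2_beta chosen so that
        the expected genetic variance (1-pi) * mean(xtx) * E[sigma2_j]
        equals h2_assumed * var(y)."""
        y = np.asarray(y, dtype=np.float64)
        vy = float(np.var(y, ddof=1)) if y.size > 1 else 1.0
        if vy <= 0:
            vy = 1.0
        mean_xtx = float(np.sum(G.xtx)) / max(G.n_individuals, 1)
        if pi >= 1.0 or mean_xtx <= 0:
            s2_beta = vy  # degenerate: no marker ever in the model
        else:
            s2_beta = (vy * h2_assumed * (nu_beta - 2.0) / nu_beta) / (
                (1.0 - pi) * mean_xtx
            )
        logger.info(
            "default hyperparameters: nu_beta=%g nu_e=%g s2_e=%g s2_beta=%g",
            nu_beta, nu_e, vy / 2.0, s2_beta,
        )
        return cls(pi=pi, nu_beta=nu_beta, s2_beta=s2_beta, nu_e=nu_e, s2_e=vy / 2.0)


@dataclass
class ModelState:
    """Current MCMC values plus the maintained residual vector."""

    mu: float
    beta: np.ndarray  # length k
    delta: np.ndarray  # length k, entries in {0, 1}
    sigma2_j: np.ndarray  # length k, positive
    sigma2_e: float
    residual: np.ndarray  # length n

    @classmethod
    def initial(cls, G: GenotypeMatrix, y: Phenotypes, hyper: Hyperparameters) -> "ModelState":
        k = G.n_markers
        mu = float(np.mean(y.y)) if y.n else 0.0
        s2e = float(np.var(y.y, ddof=1)) if y.n > 1 else hyper.s2_e
        if s2e <= 0:
            s2e = hyper.s2_e
        return cls(
            mu=mu,
            beta=np.zeros(k),
            delta=np.zeros(k, dtype=np.int8),
            sigma2_j=np.full(k, hyper.s2_beta),
            sigma2_e=s2e,
            residual=y.y - mu,
        )

    def alpha(self) -> np.ndarray:
        return self.beta * self.delta


@dataclass
class PosteriorDraws:
    """Stored post-burn-in chain samples and run metadata."""

    mu: np.ndarray  # (S,)
    sigma2_e: np.ndarray  # (S,)
    alpha: np.ndarray  # (S, k)
    delta_freq: np.ndarray  # (k,) inclusion frequency over stored draws
    iterations: np.ndarray  # (S,) 1-based iteration indices
    marker_ids: list[str]
    sampler: str
    wall_seconds: float
    n_iter: int
    burn_in: int
    thin: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return self.mu.shape[0]

    def alpha_hat(self) -> np.ndarray:
        """Posterior mean marker effects (the GEBV weights)."""
        return self.alpha.mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"iteration": self.iterations, "mu": self.mu, "sigma2_e": self.sigma2_e}
        for j, mid in enumerate(self.marker_ids):
            cols[f"alpha_{mid}"] = self.alpha[:, j]
        return pd.DataFrame(cols)


def center_genotypes(
    raw: np.ndarray,
    marker_ids: list[str] | None = None,
    individual_ids: list[str] | None = None,
    col_means: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Column-center a raw covariate matrix and cache per-column X_j'X_j.

    Missing entries (NaN) are mean-imputed before centering, so they become
    exactly zero in the centered matrix.  Any finite numeric value is
    accepted (real-valued dosages work as well as 0/1/2 codes).  Passing
    ``col_means`` centers with externally supplied means (e.g. training-set
    means applied to test genotypes) instead of the observed ones.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError("genotype matrix must be two-dimensional")
    if not np.issubdtype(raw.dtype, np.number):
        # find the first offending cell for the error message
        flat = np.asarray(raw, dtype=object)
        for i in range(flat.shape[0]):
            for j in range(flat.shape[1]):
                try:
                    float(flat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric genotype code {flat[i, j]!r} at "
                        f"row {i}, column {j}"
                    ) from None
        raw = flat.astype(np.float64)
    values = np.array(raw, dtype=np.float64, order="F")
    n, k = values.shape

    if np.any(np.isinf(values)):
        i, j = map(int, np.argwhere(np.isinf(values))[0])
        raise ValueError(f"non-finite genotype code at row {i}, column {j}")

    missing = np.isnan(values)
    n_missing = int(missing.sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotype entries", n_missing)
        with np.errstate(invalid="ignore"):
            impute_means = np.nanmean(values, axis=0)
        impute_means = np.where(np.isnan(impute_means), 0.0, impute_means)
        values[missing] = np.broadcast_to(impute_means, values.shape)[missing]

    if col_means is None:
        means = values.mean(axis=0) if n else np.zeros(k)
    else:
        means = np.asarray(col_means, dtype=np.float64)
        if means.shape != (k,):
            raise ValueError("col_means length does not match marker count")
    values -= means
    xtx = np.einsum("ij,ij->j", values, values)

    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(k)]
    n_mono = int(np.sum(xtx < MONOMORPHIC_XTX))
    if n_mono:
        logger.info("%d monomorphic markers flagged (pinned out of the model)", n_mono)
    return GenotypeMatrix(
        values=values,
        marker_ids=list(marker_ids),
        xtx=xtx,
        individual_ids=list(individual_ids) if individual_ids is not None else None,
        is_centered=True,
        col_means=means,
    )


def adjusted_rhs(state: ModelState, G: GenotypeMatrix, j: int) -> float:
    """X_j'w where w = e + X_j beta_j delta_j, computed without forming w."""
    if not 0 <= j < G.n_markers:
        raise IndexError(f"marker index {j} out of range [0, {G.n_markers})")
    xe = float(G.values[:, j] @ state.residual)
    return xe + float(G.xtx[j]) * float(state.beta[j]) * float(state.delta[j])


def update_residual(
    state: ModelState,
    G: GenotypeMatrix,
    j: int,
    alpha_old: float,
    alpha_new: float,
) -> ModelState:
    """Shift the residual for a change of alpha_j = beta_j*delta_j; O(n)."""
    diff = alpha_new - alpha_old
    if diff != 0.0:
        state.residual -= G.values[:, j] * diff
    return state


def rebuild_residual(state: ModelState, G: GenotypeMatrix, y: Phenotypes) -> ModelState:
    """Recompute the residual from scratch, guarding floating-point drift."""
    alpha = state.alpha()
    fresh = y.y - state.mu
    if G.n_markers:
        nz = np.flatnonzero(alpha)
        if nz.size:
            fresh = fresh - G.values[:, nz] @ alpha[nz]
    drift = float(np.max(np.abs(fresh - state.residual))) if y.n else 0.0
    if drift > 1e-8:
        logger.debug("residual drift %.3e corrected by rebuild", drift)
    state.residual = fresh
    return state


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_genotypes(path) -> GenotypeMatrix:
    """Read a delimited genotype file: header row of marker IDs, first
    column individual IDs, cells numeric or 'NA'."""
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                     float_precision="round_trip")
    marker_ids = [str(c) for c in df.columns]
    individual_ids = [str(i) for i in df.index]
    raw = df.to_numpy(dtype=np.float64)
    return center_genotypes(raw, marker_ids=marker_ids, individual_ids=individual_ids)


def read_phenotypes(path) -> Phenotypes:
    """Read a two-column (individual ID, trait value) delimited file.

    A header line is skipped if its second field is not numeric.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    fields = first.rstrip("\n").split(sep)
    if len(fields) < 2:
        raise ValueError(f"phenotype file {path} is not two-column delimited text")
    try:
        float(fields[1])
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"phenotype file {path} is not two-column delimited text")
    ids = [str(i) for i in df.iloc[:, 0]]
    return Phenotypes(y=df.iloc[:, 1].to_numpy(dtype=np.float64), individual_ids=ids)


def align_phenotypes(G: GenotypeMatrix, pheno: Phenotypes) -> Phenotypes:
    """Reorder phenotypes to the genotype row order, joining on IDs."""
    if G.individual_ids is None or pheno.individual_ids is None:
        if pheno.n != G.n_individuals:
            raise ValueError(
                f"phenotype count {pheno.n} does not match "
                f"{G.n_individuals} genotyped individuals and no IDs to join on"
            )
        return pheno
    lookup = {iid: i for i, iid in enumerate(pheno.individual_ids)}
    missing = [iid for iid in G.individual_ids if iid not in lookup]
    if missing:
        raise ValueError(f"no phenotype for individuals: {missing[:5]}")
    order = [lookup[iid] for iid in G.individual_ids]
    return Phenotypes(y=pheno.y[order], individual_ids=list(G.individual_ids))


def write_genotypes(path, raw: np.ndarray, marker_ids, individual_ids, sep="\t") -> None:
    df = pd.DataFrame(raw, index=list(individual_ids), columns=list(marker_ids))
    df.index.name = "id"
    df.to_csv(path, sep=sep, float_format="%.12g")


def write_phenotypes(path, pheno: Phenotypes, sep="\t") -> None:
    ids = pheno.individual_ids or [f"ind{i + 1}" for i in range(pheno.n)]
    df = pd.DataFrame({"id": ids, "y": pheno.y})
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
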