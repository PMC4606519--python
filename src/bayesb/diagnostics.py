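"""Post-chain diagnostics: effective sample size, posterior summaries,
genomic prediction accuracy and per-sampler efficiency reports."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from bayesb.data_model import GenotypeMatrix, PosteriorDraws


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive sequence estimator.

    Autocovariances are summed in adjacent pairs, truncated at the first
    negative pair and forced non-increasing; ESS = N / IACT, clipped to
    [1, N].  A zero-variance chain returns N with a warning (degenerate but
    defined).
    """
    x = np.asarray(chain, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"chain too short for ESS estimation (n={n} < 10)")
    mean_x = x.mean()
    x = x - mean_x
    var0 = float(x @ x) / n
    # constant up to accumulation rounding counts as zero-variance
    tiny = (100 * np.finfo(np.float64).eps * max(1.0, abs(mean_x))) ** 2
    if var0 < tiny or not np.isfinite(var0):
        warnings.warn("zero-variance chain: ESS defined as chain length")
        return float(n)
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]

    tau = 0.0
    prev = np.inf
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0:
            break
        gamma = min(gamma, prev)  # enforce monotone decrease
        tau += gamma
        prev = gamma
        m += 1
    iact = max(2.0 * tau - 1.0, 1.0 / n)
    return float(np.clip(n / iact, 1.0, n))


def _mcse(x: np.ndarray) -> tuple[float, float]:
    """(ESS, Monte-Carlo SE) of the mean of a chain; degenerate chains get
    ESS = N and zero SE."""
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        return float(x.size), 0.0
    ess = effective_sample_size(x)
    return ess, sd / np.sqrt(ess)


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, sd, ESS and MC standard error for mu, sigma2_e and
    every marker effect; marker rows also carry the delta inclusion
    frequency."""
    if draws.n_stored == 0:
        raise ValueError("no stored draws to summarize")
    rows = []

    def add(name: str, x: np.ndarray, incl: float | None = None) -> None:
        ess, se = _mcse(x)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "ess": ess,
                "mcse": se,
                "incl_freq": incl,
            }
        )

    add("mu", draws.mu)
    add("sigma2_e", draws.sigma2_e)
    for j, mid in enumerate(draws.marker_ids):
        add(f"alpha_{mid}", draws.alpha[:, j], incl=float(draws.delta_freq[j]))
    return pd.DataFrame(rows).set_index("parameter")


def predict_gebv(G_test: GenotypeMatrix, alpha_hat: np.ndarray, marker_ids=None) -> np.ndarray:
    """Genomic estimated breeding values X_test @ alpha_hat.

    ``marker_ids`` (if given) are the labels attached to alpha_hat and must
    match the test genotype markers one-to-one and in order.
    """
    alpha_hat = np.asarray(alpha_hat, dtype=np.float64)
    if alpha_hat.shape[0] != G_test.n_markers:
        raise ValueError(
            f"{alpha_hat.shape[0]} effects for {G_test.n_markers} markers"
        )
    if marker_ids is not None:
        offenders = [
            (a, b) for a, b in zip(marker_ids, G_test.marker_ids) if str(a) != str(b)
        ]
        if offenders:
            raise ValueError(f"marker mismatch between effects and genotypes: {offenders[:5]}")
    return G_test.values @ alpha_hat


def prediction_accuracy(gebv: np.ndarray, y_test: np.ndarray) -> float:
    """Pearson correlation between GEBV and held-out phenotypes."""
    gebv = np.asarray(gebv, dtype=np.float64)
    y_test = np.asarray(y_test, dtype=np.float64)
    if gebv.shape != y_test.shape:
        raise ValueError("gebv and phenotype vectors differ in length")
    if gebv.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(gebv) == 0 or np.std(y_test) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(gebv, y_test)[0, 1])


@dataclass
class EfficiencyReport:
    """Per-sampler efficiency summary (ESS/s is hardware-dependent)."""

    sampler: str
    chain_length: int
    wall_seconds: float
    ess_sigma2_e: float
    ess_per_second: float
    posterior_mean_mu: float
    posterior_mean_sigma2_e: float
    prediction_accuracy: float | None = None
    accuracy_vs_truth: float | None = None
    hardware_dependent: bool = True  # flags ess_per_second

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "EfficiencyReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def efficiency_report(
    draws: PosteriorDraws,
    G_test: GenotypeMatrix | None = None,
    y_test: np.ndarray | None = None,
    breeding_values: np.ndarray | None = None,
) -> EfficiencyReport:
    """Assemble the per-sampler report; prediction accuracy is included when
    a test set is supplied, and accuracy against true breeding values when
    simulation truth is available."""
    if draws.wall_seconds <= 0:
        raise ValueError("draws carry no wall-clock duration")
    ess = effective_sample_size(draws.sigma2_e)
    acc = acc_truth = None
    if G_test is not None and y_test is not None:
        gebv = predict_gebv(G_test, draws.alpha_hat())
        acc = prediction_accuracy(gebv, y_test)
        if breeding_values is not None:
            acc_truth = prediction_accuracy(gebv, breeding_values)
    return EfficiencyReport(
        sampler=draws.sampler,
        chain_length=draws.n_iter,
        wall_seconds=draws.wall_seconds,
        ess_sigma2_e=ess,
        ess_per_second=ess / draws.wall_seconds,
        posterior_mean_mu=float(np.mean(draws.mu)),
        posterior_mean_sigma2_e=float(np.mean(draws.sigma2_e)),
        prediction_accuracy=acc,
        accuracy_vs_truth=acc_truth,
    )
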