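"""Posterior functionals and summaries of variance-component chains.

Heritability and genetic/phenotypic correlations are computed per
retained sample (posterior of the functional), never as a ratio of
posterior means.  Summaries follow the usual reporting layout: mean,
median, SD, Monte-Carlo standard error by batch means, equal-tailed 95%
credible interval, and the 95% highest-posterior-density interval as
the shortest contiguous window of sorted samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneticParameterSummary",
    "heritability",
    "genetic_correlation",
    "phenotypic_correlation",
    "summarize_chain",
    "hpdi",
    "mcse_batch_means",
]


def _diag(samples: np.ndarray, i: int) -> np.ndarray:
    s = np.asarray(samples, dtype=float)
    if s.ndim == 2:
        s = s[None, :, :]
    return s[..., i, i]


def heritability(g0_samples, r0_samples, trait_index: int = 0) -> np.ndarray:
    """h² = sigma²_a / (sigma²_a + sigma²_e), per retained sample."""
    va = _diag(g0_samples, trait_index)
    ve = _diag(r0_samples, trait_index)
    if np.any(va <= 0) or np.any(ve <= 0):
        raise ValueError("non-positive variance sample; matrices must be PD")
    return np.squeeze(va / (va + ve))


def genetic_correlation(g0_samples, i: int = 0, j: int = 1) -> np.ndarray:
    """r_g = sigma_a(i,j) / sqrt(sigma²_a(i) sigma²_a(j)), per sample."""
    s = np.asarray(g0_samples, dtype=float)
    if s.ndim == 2:
        s = s[None, :, :]
    vi, vj = s[..., i, i], s[..., j, j]
    if np.any(vi <= 0) or np.any(vj <= 0):
        raise ValueError("zero or negative genetic variance for a trait")
    return np.squeeze(s[..., i, j] / np.sqrt(vi * vj))


def phenotypic_correlation(g0_samples, r0_samples, i: int = 0, j: int = 1) -> np.ndarray:
    """Correlation implied by P0 = G0 + R0, per sample."""
    g = np.asarray(g0_samples, dtype=float)
    r = np.asarray(r0_samples, dtype=float)
    if g.ndim == 2:
        g, r = g[None, :, :], r[None, :, :]
    p = g + r
    vi, vj = p[..., i, i], p[..., j, j]
    if np.any(vi <= 0) or np.any(vj <= 0):
        raise ValueError("zero or negative phenotypic variance for a trait")
    return np.squeeze(p[..., i, j] / np.sqrt(vi * vj))


@dataclass(frozen=True)
class GeneticParameterSummary:
    name: str
    mean: float
    median: float
    sd: float
    mcse: float
    bci_lower: float
    bci_upper: float
    hpdi_lower: float
    hpdi_upper: float
    multimodal_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "trait": self.name,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "mcse": self.mcse,
            "bci_2.5": self.bci_lower,
            "bci_97.5": self.bci_upper,
            "hpdi_2.5": self.hpdi_lower,
            "hpdi_97.5": self.hpdi_upper,
        }


def mcse_batch_means(samples) -> float:
    """Monte-Carlo standard error by non-overlapping batch means.

    Uses ~sqrt(n) batches of equal size (trailing remainder dropped):
    MCSE = sd(batch means) / sqrt(n_batches).
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    nb = max(int(math.floor(math.sqrt(n))), 2)
    size = n // nb
    means = x[: nb * size].reshape(nb, size).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(nb))


def hpdi(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(level*n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    w = int(math.ceil(level * n))
    w = min(max(w, 1), n)
    if w == n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def summarize_chain(samples, name: str = "", level: float = 0.95) -> GeneticParameterSummary:
    """Mean/median/SD, batch-means MCSE, equal-tailed BCI and HPDI.

    A ``multimodal_flag`` is raised when the HPDI comes out wider than
    the equal-tailed interval, which cannot happen for a unimodal
    posterior and signals that the contiguous-window HPD assumption is
    suspect for these samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.reshape(-1)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to summarize")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    h_lo, h_hi = hpdi(x, level)
    flag = (h_hi - h_lo) > (hi - lo) * (1 + 1e-9)
    if flag:
        warnings.warn(
            f"HPDI wider than BCI for {name or 'chain'}; "
            "posterior may be multimodal",
            stacklevel=2,
        )
    return GeneticParameterSummary(
        name=name,
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=float(np.std(x, ddof=1)),
        mcse=mcse_batch_means(x),
        bci_lower=float(lo),
        bci_upper=float(hi),
        hpdi_lower=h_lo,
        hpdi_upper=h_hi,
        multimodal_flag=bool(flag),
    )
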