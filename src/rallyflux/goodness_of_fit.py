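"""Kolmogorov–Smirnov comparison of observed vs expected DMA distributions.

For one match, the empirical CDF of its valid DMA values is compared with
the exact expected CDF at the match's own overall winning probability. Both
CDFs are evaluated only at the 17 grid points k/16, which handles ties on
the discrete support cleanly; the K-S distance is

    d = max_k | ECDF(k/16) - F_expected(k/16) |.

Two p-values are offered. The ``asymptotic`` method applies the standard
one-sample K-S null distribution at (d, n). That law assumes a continuous
distribution and independent observations, neither of which holds here
(discrete 17-point support; overlapping 7-rally windows make consecutive
DMA values strongly autocorrelated), so it is best viewed as a screening
value. The ``monte_carlo`` method simulates whole iid Bernoulli matches of
the same length and winning probability, recomputes the DMA and its d per
replicate, and reports the fraction of replicate distances at least as
large as the observed one — this null reproduces both the discreteness and
the autocorrelation and is the recommended method.

Because the observed d is measured against an expected distribution whose
parameter is the match's *own* estimated winning probability, each
replicate's d is likewise measured against the expected distribution at the
replicate's own estimated probability (the parametric-bootstrap analogue of
the Lilliefors correction). Without this re-estimation the replicate
distances are stochastically larger than the observed one and the test
never rejects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .dma_core import DMA_KERNEL_W4, DMASeries
from .errors import UsageError
from .expected_dist import (
    ExpectedDMADistribution,
    expected_cdf,
    expected_dma_distribution,
)

__all__ = ["KSTestResult", "ks_distance", "ks_test"]


@dataclass(frozen=True)
class KSTestResult:
    """Result of the one-sample K-S comparison for one match."""

    d: float
    p_value: float
    method: Literal["asymptotic", "monte_carlo"]
    n_obs: int
    mc_replicates: int | None = None
    seed: int | None = None


def _grid_numerators(dma: DMASeries) -> np.ndarray:
    if dma.n_valid == 0:
        raise UsageError("empty DMA series")
    if dma.numerators is None or dma.denominator != 16:
        raise UsageError(
            "K-S comparison requires a valid-only window-4 DMA on the 17-point grid"
        )
    return dma.numerators


def _ecdf_on_grid(numerators: np.ndarray) -> np.ndarray:
    counts = np.bincount(numerators, minlength=17)
    return np.cumsum(counts) / numerators.size


def ks_distance(dma: DMASeries, expected: ExpectedDMADistribution) -> float:
    """Maximum CDF distance between observed and expected DMA on the grid."""
    ecdf = _ecdf_on_grid(_grid_numerators(dma))
    return float(np.max(np.abs(ecdf - expected_cdf(expected))))


def _simulated_distances(
    n_rallies: int, p: float, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """K-S distances of iid Bernoulli(p) replicate matches, vectorised.

    Each replicate's distance is measured against the expected CDF at the
    replicate's own estimated winning probability, mirroring how the
    observed match is treated.
    """
    x = (rng.random((replicates, n_rallies)) < p).astype(np.int64)
    n_valid = n_rallies - 6
    nums = sum(int(w) * x[:, i : i + n_valid] for i, w in enumerate(DMA_KERNEL_W4))
    rows = np.repeat(np.arange(replicates), n_valid)
    counts = np.bincount(
        rows * 17 + nums.ravel(), minlength=replicates * 17
    ).reshape(replicates, 17)
    ecdf = np.cumsum(counts, axis=1) / n_valid
    wins = x.sum(axis=1)
    uniq, inverse = np.unique(wins, return_inverse=True)
    cdf_by_p = np.stack(
        [expected_cdf(expected_dma_distribution(w / n_rallies)) for w in uniq]
    )
    return np.max(np.abs(ecdf - cdf_by_p[inverse]), axis=1)


def ks_test(
    dma: DMASeries,
    expected: ExpectedDMADistribution,
    method: Literal["asymptotic", "monte_carlo"] = "asymptotic",
    mc_replicates: int = 2000,
    seed: int | None = None,
) -> KSTestResult:
    """One-sample K-S test of a match's DMA values against the iid model.

    ``expected`` should be built from the match's own overall winning
    probability. See the module docstring for the two p-value methods.
    """
    d = ks_distance(dma, expected)
    n = dma.n_valid
    if method == "asymptotic":
        p_value = float(np.clip(stats.kstwo.sf(d, n), 0.0, 1.0))
        return KSTestResult(d=d, p_value=p_value, method="asymptotic", n_obs=n)
    if method != "monte_carlo":
        raise UsageError(f"unknown method {method!r}")
    if mc_replicates < 100:
        raise UsageError(
            f"mc_replicates must be >= 100 for a stable p-value, got {mc_replicates}"
        )
    rng = np.random.default_rng(seed)
    d_rep = _simulated_distances(
        n_rallies=n + 6, p=expected.p, replicates=mc_replicates, rng=rng
    )
    # 1e-12 slack so replicate distances equal to d up to rounding count as ties
    p_value = float(np.mean(d_rep >= d - 1e-12))
    return KSTestResult(
        d=d, p_value=p_value, method="monte_carlo", n_obs=n,
        mc_replicates=mc_replicates, seed=seed,
    )
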