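"""Exact expected DMA distribution under independent rallies.

If rally outcomes are iid Bernoulli(p), the window-4 DMA of any rally is a
fixed weighted sum of the 7 surrounding outcomes, so its marginal law can
be computed exactly: enumerate all 2^7 = 128 win/loss sequences of length
7, give a sequence with k wins probability p^k (1-p)^(7-k), map each
sequence through the DMA kernel (1,2,3,4,3,2,1)/16, and accumulate the
probabilities per attainable value. The support is the 17-point grid
{k/16 : k = 0..16}; zero-probability support points (possible only at
p in {0, 1}) are retained so any two distributions live on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dma_core import DMA_KERNEL_W4
from .errors import UsageError

__all__ = [
    "ExpectedDMADistribution",
    "enumerate_sequences",
    "expected_dma_distribution",
    "expected_cdf",
]

_ENUM_GUARD = 24  # 2^24 rows is the largest enumeration we allow


def enumerate_sequences(length: int = 7) -> np.ndarray:
    """All binary sequences of the given length, one per row, lexicographic.

    Returns an int8 array of shape ``(2**length, length)``.
    """
    if length < 1:
        raise UsageError(f"length must be >= 1, got {length}")
    if length > _ENUM_GUARD:
        raise UsageError(
            f"refusing to enumerate 2^{length} sequences (guard at {_ENUM_GUARD})"
        )
    codes = np.arange(2**length, dtype=np.int64)[:, None]
    shifts = np.arange(length - 1, -1, -1)
    return ((codes >> shifts) & 1).astype(np.int8)


@dataclass(frozen=True)
class ExpectedDMADistribution:
    """Exact law of the window-4 DMA under iid Bernoulli(p) rallies.

    ``support`` is the ascending 17-point grid k/16; ``probabilities`` sum
    to 1 and the distribution's mean equals ``p`` exactly (the DMA is a
    convex combination of Bernoulli(p) variables).
    """

    support: np.ndarray
    probabilities: np.ndarray
    p: float

    def __post_init__(self) -> None:
        for name in ("support", "probabilities"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def cdf(self) -> np.ndarray:
        """Cumulative probabilities over the support grid."""
        return np.cumsum(self.probabilities)

    def mean(self) -> float:
        return float(self.support @ self.probabilities)


def expected_dma_distribution(p: float) -> ExpectedDMADistribution:
    """Exact expected DMA distribution for overall winning probability p."""
    if not 0.0 <= p <= 1.0:
        raise UsageError(f"winning probability must be in [0, 1], got {p}")
    seqs = enumerate_sequences(7)
    k_wins = seqs.sum(axis=1).astype(np.int64)
    numerators = seqs.astype(np.int64) @ DMA_KERNEL_W4  # 0..16
    with np.errstate(invalid="ignore"):
        seq_probs = np.power(float(p), k_wins) * np.power(1.0 - float(p), 7 - k_wins)
    probabilities = np.bincount(numerators, weights=seq_probs, minlength=17)
    support = np.arange(17) / 16.0
    return ExpectedDMADistribution(support=support, probabilities=probabilities, p=float(p))


def expected_cdf(dist: ExpectedDMADistribution) -> np.ndarray:
    """Cumulative distribution over the 17-point support grid."""
    return dist.cdf
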