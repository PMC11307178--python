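"""Monte-Carlo null distribution of DMA kurtosis and the per-match z-test.

The kurtosis of a match's DMA distribution measures its peakedness without
assuming any parametric form: a flatter (or bi-/multi-modal) distribution —
excess kurtosis below expectation — signals large within-match
fluctuations, a steeper one signals unusually stable play. To decide
whether an observed kurtosis is compatible with independent rallies, the
null distribution of the kurtosis is simulated for the match at hand:

1. draw a long stream (default 1,000,000) of iid Bernoulli(p) outcomes at
   the match's overall winning probability;
2. compute the DMA over the whole stream;
3. cut the valid DMA values into consecutive non-overlapping segments —
   "Monte Carlo matches" — of the same length as the match's own valid DMA
   series (a 10^6 stream at segment length 100 yields 9,999 segments; the
   uncut arithmetic is 10,000);
4. compute the excess kurtosis of each segment (zero-variance segments are
   dropped and counted; more than 1% dropped aborts the run since the
   normal approximation is then suspect);
5. take the mean and SD of the segment kurtoses;
6. z-test the observed kurtosis against that mean and SD, two-sided.

Segmenting the DMA series (rather than the rally stream) makes the
simulated segments exchangeable with the observed match's DMA series under
the null, so observed and simulated kurtoses are computed on identically
sized samples by the identical formula.

The kurtosis formula is the sample excess kurtosis with the standard
small-sample bias adjustment (``variant="adjusted"``, the default of major
statistics packages); a plain moment-based variant is available for
sensitivity checks. The same variant is always applied to the observed
match and the simulated segments, so the z statistic is internally
consistent under either choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .dma_core import DMA_KERNEL_W4, DMASeries
from .errors import DegenerateInputError, UsageError

__all__ = [
    "KurtosisNull",
    "KurtosisTestResult",
    "sample_kurtosis",
    "simulate_kurtosis_null",
    "kurtosis_z_test",
    "z_test_from_value",
    "KurtosisNullCache",
]

KurtosisVariant = Literal["adjusted", "moment"]


def sample_kurtosis(values, variant: KurtosisVariant = "adjusted") -> float:
    """Excess kurtosis of a sample (0 in expectation for normal data).

    ``adjusted`` applies the small-sample bias correction; ``moment`` is the
    plain fourth-moment ratio minus 3.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise UsageError(f"kurtosis needs at least 4 values, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateInputError("kurtosis is undefined for a constant sample")
    return float(stats.kurtosis(v, fisher=True, bias=(variant == "moment")))


@dataclass(frozen=True)
class KurtosisNull:
    """Simulated null distribution of segment DMA kurtosis for one (p, n).

    ``n_rallies`` is the segment length in valid DMA values (set to the
    match's own count so observed and simulated kurtoses are exchangeable
    under the null). ``n_segments`` is floor((total_draws - 6)/n_rallies);
    ``n_dropped`` of those had zero variance and were excluded from
    ``null_mean``/``null_sd``.
    """

    null_mean: float
    null_sd: float
    n_segments: int
    n_rallies: int
    p: float
    total_draws: int
    seed: int | None
    variant: KurtosisVariant = "adjusted"
    n_dropped: int = 0


@dataclass(frozen=True)
class KurtosisTestResult:
    """Two-sided z-test of an observed DMA kurtosis against its null."""

    observed_kurtosis: float
    z: float
    p_two_sided: float
    significant_at_05: bool
    null: KurtosisNull


def simulate_kurtosis_null(
    p: float,
    n_rallies: int,
    total_draws: int = 1_000_000,
    seed: int | None = None,
    variant: KurtosisVariant = "adjusted",
) -> KurtosisNull:
    """Simulate the null kurtosis distribution of DMA segments.

    Parameters
    ----------
    p:
        Overall point-winning probability, strictly inside (0, 1).
    n_rallies:
        Segment length in valid DMA values (use the match's valid DMA
        count); at least 20.
    total_draws:
        Length of the simulated rally stream (default 10^6); must be at
        least ``100 * n_rallies`` so the null mean/SD are stable.
    seed:
        Seed for the PCG64 generator (``numpy.random.default_rng``).
    """
    if not 0.0 < p < 1.0:
        raise DegenerateInputError(
            f"kurtosis null needs 0 < p < 1 (constant streams have no kurtosis), got {p}"
        )
    if n_rallies < 20:
        raise UsageError(f"segment length must be >= 20 DMA values, got {n_rallies}")
    if total_draws < 100 * n_rallies:
        raise UsageError(
            f"total_draws must be >= 100 * n_rallies = {100 * n_rallies}, got {total_draws}"
        )
    rng = np.random.default_rng(seed)
    x = (rng.random(total_draws) < p).astype(np.int64)
    nums = np.convolve(x, DMA_KERNEL_W4, mode="valid")  # kurtosis is scale-free
    n_valid = total_draws - 6
    n_segments = n_valid // n_rallies
    seg = nums[: n_segments * n_rallies].reshape(n_segments, n_rallies).astype(float)
    keep = seg.var(axis=1) > 0
    n_dropped = int(n_segments - keep.sum())
    if n_dropped > 0.01 * n_segments:
        raise DegenerateInputError(
            f"{n_dropped}/{n_segments} zero-variance segments at p={p}; the normal "
            "approximation of the kurtosis null is unreliable this close to 0 or 1"
        )
    kurt = stats.kurtosis(seg[keep], axis=1, fisher=True, bias=(variant == "moment"))
    return KurtosisNull(
        null_mean=float(np.mean(kurt)),
        null_sd=float(np.std(kurt, ddof=1)),
        n_segments=n_segments,
        n_rallies=n_rallies,
        p=float(p),
        total_draws=total_draws,
        seed=seed,
        variant=variant,
        n_dropped=n_dropped,
    )


def z_test_from_value(observed_kurtosis: float, null: KurtosisNull) -> KurtosisTestResult:
    """Two-sided z-test of a precomputed kurtosis against a simulated null."""
    if null.null_sd <= 0:
        raise DegenerateInputError("null kurtosis distribution has zero spread")
    z = (observed_kurtosis - null.null_mean) / null.null_sd
    p_two = float(2.0 * stats.norm.sf(abs(z)))
    return KurtosisTestResult(
        observed_kurtosis=float(observed_kurtosis),
        z=float(z),
        p_two_sided=p_two,
        significant_at_05=bool(p_two < 0.05),
        null=null,
    )


def kurtosis_z_test(dma: DMASeries, null: KurtosisNull) -> KurtosisTestResult:
    """z-test of a match's observed DMA kurtosis against its simulated null.

    The null should have been built with the match's own winning
    probability and valid DMA count (see :class:`KurtosisNullCache`).
    """
    observed = sample_kurtosis(dma.values, variant=null.variant)
    return z_test_from_value(observed, null)


class KurtosisNullCache:
    """Deterministic cache of kurtosis nulls keyed by (p, segment length).

    Matches sharing an estimated winning probability and length need the
    same null, and simulating a fresh 10^6-draw stream per match would be
    wasteful. The per-null seed is derived from the master seed and the key
    via :class:`numpy.random.SeedSequence`, so a batch is reproducible
    regardless of the order in which matches are analysed.
    """

    def __init__(
        self,
        master_seed: int = 0,
        total_draws: int = 1_000_000,
        variant: KurtosisVariant = "adjusted",
    ) -> None:
        self.master_seed = master_seed
        self.total_draws = total_draws
        self.variant = variant
        self._cache: dict[tuple[float, int], KurtosisNull] = {}

    def get(self, p: float, n_rallies: int) -> KurtosisNull:
        key = (round(float(p), 12), int(n_rallies))
        if key not in self._cache:
            ss = np.random.SeedSequence(
                (self.master_seed, n_rallies, int(round(p * 1_000_000_000)))
            )
            child_seed = int(ss.generate_state(1)[0])
            self._cache[key] = simulate_kurtosis_null(
                p=p,
                n_rallies=n_rallies,
                total_draws=self.total_draws,
                seed=child_seed,
                variant=self.variant,
            )
        return self._cache[key]
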