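"""Double moving average (DMA) of rally outcomes: momentary playing strength.

A static point-winning rate hides everything that happens *during* a match.
The DMA is a compromise between the raw rally-by-rally 0/1 sequence (too
noisy) and the overall winning probability (too static): a simple moving
average of window ``N`` is computed in the forward direction,

    M_i = (y_i + y_{i-1} + ... + y_{i-N+1}) / N,

and a second, backward moving average of the next ``N`` values of M
synchronises the smoother with the match:

    DMA_i = (M_i + M_{i+1} + ... + M_{i+N-1}) / N.

With the default window N = 4 this composition is identical to a symmetric
7-term weighted sum of the outcomes,

    DMA_i = (x_{i-3} + 2 x_{i-2} + 3 x_{i-1} + 4 x_i
             + 3 x_{i+1} + 2 x_{i+2} + x_{i+3}) / 16,

so every DMA value is an exact multiple of 1/16 and the statistic can take
exactly 17 distinct values in [0, 1]. Because the denominators are powers
of two, the float values stored here are exact; integer numerators are kept
alongside them so downstream code can compare values on the 17-point grid
without any floating tolerance.

Under the default "valid-only" edge policy the DMA is defined for rallies
i in [N, n-N+1] (i.e. [4, n-3]), giving n-6 values for a match of n
rallies. The alternative "shrink" policy shortens the windows at both ends
so a value exists for every rally; those values leave the 1/16 grid and are
excluded from the grid-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InsufficientDataError, UsageError
from .rally_io import RallyOutcomeSeries

__all__ = [
    "MovingAverageSeries",
    "DMASeries",
    "FluctuationSummary",
    "moving_average",
    "double_moving_average",
    "dma_weighted",
    "summarize_fluctuation",
    "triangular_kernel",
]

#: Weights of the composed window-4 DMA as a single 7-term kernel.
DMA_KERNEL_W4 = np.array([1, 2, 3, 4, 3, 2, 1], dtype=np.int64)


def triangular_kernel(window: int) -> np.ndarray:
    """Integer weights of the composed double moving average of ``window``.

    The composition of two boxcar averages of length ``window`` is a
    triangular kernel of length ``2*window - 1`` with weights
    1, 2, ..., window, ..., 2, 1 and divisor ``window**2``.
    """
    up = np.arange(1, 2 * window)
    return np.minimum(up, 2 * window - up).astype(np.int64)


@dataclass(frozen=True)
class MovingAverageSeries:
    """Forward (backward-looking) simple moving average of rally outcomes.

    ``values[j]`` is M_i for rally i = ``first_valid_index + j``; each value
    is an exact multiple of ``1/window``.
    """

    values: np.ndarray
    window: int
    first_valid_index: int
    numerators: np.ndarray  # integer window sums; values = numerators/window

    @property
    def n_valid(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class DMASeries:
    """Double moving average series with its window metadata.

    ``values[j]`` is the DMA at rally ``first_valid_index + j`` (1-based).
    Under the valid-only policy ``numerators`` holds the exact integer
    numerators over ``denominator = window**2``; under the shrink policy
    values are no longer on a fixed grid and ``numerators`` is ``None``.
    """

    values: np.ndarray
    window: int = 4
    first_valid_index: int = 4
    last_valid_index: int = 4
    edge_policy: Literal["valid-only", "shrink"] = "valid-only"
    numerators: np.ndarray | None = None
    denominator: int = 16

    @property
    def n_valid(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class FluctuationSummary:
    """Per-match descriptive statistics of the DMA course.

    ``sd_dma`` is the sample standard deviation (ddof=1; 0 for a single
    value), ``iqr_dma`` the interquartile range with quartiles by linear
    interpolation, ``cv_dma`` the coefficient of variation sd/mean (0 when
    the series is constant at 0). ``touched_upper``/``touched_lower`` flag
    whether the DMA reached 1 (a streak of 7 straight wins) or 0 (7
    straight losses) anywhere in the match. ``wp`` is the overall
    point-winning probability of the focal player.
    """

    mean_dma: float
    sd_dma: float
    iqr_dma: float
    cv_dma: float
    touched_upper: bool
    touched_lower: bool
    n_valid: int
    wp: float


def moving_average(series: RallyOutcomeSeries, window: int = 4) -> MovingAverageSeries:
    """Backward-looking simple moving average M_i of the outcome series.

    Defined for rallies i in [window, n]; M_i averages outcomes
    i-window+1 .. i.
    """
    if window < 1:
        raise UsageError(f"window must be >= 1, got {window}")
    if series.n < window:
        raise InsufficientDataError(
            f"need at least {window} rallies for a window-{window} moving "
            f"average, got {series.n}"
        )
    x = series.outcomes.astype(np.int64)
    sums = np.convolve(x, np.ones(window, dtype=np.int64), mode="valid")
    return MovingAverageSeries(
        values=sums / window,
        window=window,
        first_valid_index=window,
        numerators=sums,
    )


def double_moving_average(
    series: RallyOutcomeSeries,
    window: int = 4,
    edge_policy: Literal["valid-only", "shrink"] = "valid-only",
) -> DMASeries:
    """DMA of the outcome series: forward MA followed by a backward MA.

    DMA_i averages M_i .. M_{i+window-1}; under the valid-only policy it is
    defined for i in [window, n-window+1] (n - 2*window + 2 values).
    """
    if edge_policy == "shrink":
        return _dma_shrink(series, window)
    if window < 1:
        raise UsageError(f"window must be >= 1, got {window}")
    n_min = 2 * window - 1
    if series.n < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} rallies for a window-{window} DMA, got {series.n}"
        )
    ma = moving_average(series, window)
    # backward average over the next `window` MA values (integer arithmetic)
    nums = np.convolve(ma.numerators, np.ones(window, dtype=np.int64), mode="valid")
    denom = window * window
    return DMASeries(
        values=nums / denom,
        window=window,
        first_valid_index=window,
        last_valid_index=series.n - window + 1,
        edge_policy="valid-only",
        numerators=nums,
        denominator=denom,
    )


def _dma_shrink(series: RallyOutcomeSeries, window: int = 4) -> DMASeries:
    """DMA with windows shrunk at the edges so every rally gets a value.

    The first MA uses outcomes max(1, i-window+1)..i; the second averages
    the MAs at i..min(i+window-1, n). Values are not multiples of
    1/window**2, so no grid numerators are attached.
    """
    if window < 1:
        raise UsageError(f"window must be >= 1, got {window}")
    x = series.outcomes.astype(float)
    n = series.n
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(1, n + 1)
    lo = np.maximum(i - window, 0)
    ma = (csum[i] - csum[lo]) / (i - lo)
    mcs = np.concatenate([[0.0], np.cumsum(ma)])
    hi = np.minimum(i + window - 1, n)
    dma = (mcs[hi] - mcs[i - 1]) / (hi - i + 1)
    return DMASeries(
        values=dma,
        window=window,
        first_valid_index=1,
        last_valid_index=n,
        edge_policy="shrink",
        numerators=None,
        denominator=window * window,
    )


def dma_weighted(series: RallyOutcomeSeries, window: int = 4) -> DMASeries:
    """DMA computed directly as a weighted sum of 2*window-1 outcomes.

    For the default window 4:

        DMA_i = (x_{i-3} + 2x_{i-2} + 3x_{i-1} + 4x_i
                 + 3x_{i+1} + 2x_{i+2} + x_{i+3}) / 16.

    Elementwise identical to :func:`double_moving_average`; the two
    implementations are independent code paths kept as mutual checks.
    """
    if window < 1:
        raise UsageError(f"window must be >= 1, got {window}")
    n_min = 2 * window - 1
    if series.n < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} rallies for a window-{window} DMA, got {series.n}"
        )
    kernel = triangular_kernel(window)
    x = series.outcomes.astype(np.int64)
    # np.convolve flips the kernel; irrelevant here since it is symmetric
    nums = np.convolve(x, kernel, mode="valid")
    denom = window * window
    return DMASeries(
        values=nums / denom,
        window=window,
        first_valid_index=window,
        last_valid_index=series.n - window + 1,
        edge_policy="valid-only",
        numerators=nums,
        denominator=denom,
    )


def summarize_fluctuation(
    dma: DMASeries, series: RallyOutcomeSeries
) -> FluctuationSummary:
    """Descriptive fluctuation statistics of one match's DMA course."""
    v = dma.values
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = float(q3 - q1)
    cv = sd / mean if mean > 0 else 0.0
    return FluctuationSummary(
        mean_dma=mean,
        sd_dma=sd,
        iqr_dma=iqr,
        cv_dma=cv,
        touched_upper=bool(np.max(v) == 1.0),
        touched_lower=bool(np.min(v) == 0.0),
        n_valid=dma.n_valid,
        wp=series.wp,
    )
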