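"""DMA computation: exactness, dual-route equivalence, symmetries, summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rallyflux import (
    InsufficientDataError,
    RallyOutcomeSeries,
    dma_weighted,
    double_moving_average,
    moving_average,
    summarize_fluctuation,
)
from rallyflux.synthetic import generate_iid

binary_series = st.lists(st.integers(0, 1), min_size=7, max_size=200).map(
    RallyOutcomeSeries
)


class TestMovingAverage:
    def test_constant_series(self):
        ma = moving_average(RallyOutcomeSeries([1] * 7), window=4)
        assert np.array_equal(ma.values, [1, 1, 1, 1])
        assert ma.first_valid_index == 4

    def test_alternating_series_by_hand(self):
        # means of (1,0,1,0) and (0,1,0,1)
        ma = moving_average(RallyOutcomeSeries([1, 0, 1, 0, 1]), window=4)
        assert np.array_equal(ma.values, [0.5, 0.5])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            moving_average(RallyOutcomeSeries([1, 0]), window=4)

    def test_values_are_multiples_of_one_over_window(self):
        s = generate_iid(0.5, 40, seed=7)
        ma = moving_average(s, window=4)
        assert np.array_equal(ma.numerators, ma.values * 4)
        assert ma.n_valid == 40 - 4 + 1


class TestDoubleMovingAverage:
    def test_seven_wins_single_value(self):
        dma = double_moving_average(RallyOutcomeSeries([1] * 7))
        assert dma.n_valid == 1
        assert dma.values[0] == 1.0
        assert dma.first_valid_index == 4
        assert dma.last_valid_index == 4

    def test_valid_range_and_length(self):
        dma = double_moving_average(RallyOutcomeSeries([1, 0] * 6))
        assert dma.n_valid == 12 - 6
        assert (dma.first_valid_index, dma.last_valid_index) == (4, 9)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            double_moving_average(RallyOutcomeSeries([1] * 6))

    def test_exhaustive_weighted_formula_over_all_length7_vectors(self):
        # DMA_4 = (x1 + 2x2 + 3x3 + 4x4 + 3x5 + 2x6 + x7)/16, all 128 cases
        weights = [1, 2, 3, 4, 3, 2, 1]
        for bits in itertools.product((0, 1), repeat=7):
            expected = sum(w * x for w, x in zip(weights, bits)) / 16
            dma = double_moving_average(RallyOutcomeSeries(list(bits)))
            assert dma.values[0] == expected

    def test_block_series_matches_weighted_route(self):
        s = RallyOutcomeSeries([1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1])
        assert np.array_equal(
            double_moving_average(s).numerators, dma_weighted(s).numerators
        )


class TestWeightedDMA:
    def test_all_zero(self):
        dma = dma_weighted(RallyOutcomeSeries([0] * 9))
        assert np.all(dma.values == 0)

    def test_single_win_center_weight(self):
        dma = dma_weighted(RallyOutcomeSeries([0, 0, 0, 1, 0, 0, 0]))
        assert dma.values[0] == 4 / 16

    @given(binary_series)
    def test_equals_composed_route_exactly(self, series):
        a = double_moving_average(series)
        b = dma_weighted(series)
        assert np.array_equal(a.numerators, b.numerators)
        assert np.array_equal(a.values, b.values)

    @given(binary_series)
    def test_support_is_sixteenths(self, series):
        nums = dma_weighted(series).numerators
        assert nums.min() >= 0 and nums.max() <= 16

    @given(binary_series)
    def test_complement_symmetry(self, series):
        # the loser's DMA mirrors the winner's about 0.5
        a = dma_weighted(series).values
        b = dma_weighted(series.complement()).values
        assert np.array_equal(b, 1.0 - a)


def test_dma_mean_converges_to_p():
    p, n = 0.577, 100_000
    s = generate_iid(p, n, seed=11)
    dma = double_moving_average(s)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(dma.values.mean() - p) < 3 * se


class TestShrinkPolicy:
    def test_covers_every_rally_and_stays_in_range(self):
        s = generate_iid(0.6, 30, seed=3)
        dma = double_moving_average(s, edge_policy="shrink")
        assert dma.n_valid == 30
        assert (dma.first_valid_index, dma.last_valid_index) == (1, 30)
        assert dma.numerators is None
        assert np.all((dma.values >= 0) & (dma.values <= 1))

    def test_agrees_with_valid_only_in_the_interior(self):
        s = generate_iid(0.4, 25, seed=4)
        full = double_moving_average(s).values
        shrunk = double_moving_average(s, edge_policy="shrink").values
        assert np.allclose(shrunk[3:-3], full)


class TestSummarize:
    def test_constant_dma(self):
        s = RallyOutcomeSeries([1] * 10)
        summ = summarize_fluctuation(double_moving_average(s), s)
        assert summ.sd_dma == 0 and summ.iqr_dma == 0 and summ.cv_dma == 0
        assert summ.wp == 1 and summ.touched_upper and not summ.touched_lower

    def test_iqr_by_linear_interpolation(self):
        # quartiles of [0.25, 0.5, 0.75, 1.0]: q1 = 0.4375, q3 = 0.8125
        from rallyflux.dma_core import DMASeries

        dma = DMASeries(
            values=np.array([0.25, 0.5, 0.75, 1.0]),
            numerators=np.array([4, 8, 12, 16]),
            first_valid_index=4, last_valid_index=7,
        )
        series = RallyOutcomeSeries([1, 0] * 5)
        summ = summarize_fluctuation(dma, series)
        assert summ.iqr_dma == pytest.approx(0.375)
        assert summ.touched_upper and not summ.touched_lower

    def test_boundary_touch_flags(self):
        s = RallyOutcomeSeries([1] * 7 + [0] * 7)
        summ = summarize_fluctuation(double_moving_average(s), s)
        assert summ.touched_upper and summ.touched_lower
        assert summ.n_valid == 8
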