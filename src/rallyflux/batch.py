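"""Batch orchestration: run the full fluctuation analysis over many matches.

For each match this computes the DMA course and its descriptive summary,
builds the exact expected DMA distribution at the match's own overall
winning probability, runs the K-S comparison, and (where defined) the
Monte-Carlo kurtosis z-test with the null built at the match's own
(p, valid-DMA-count). Results are collected into one tidy DataFrame plus
tournament-level significance proportions.

No multiple-testing correction is applied to the per-match flags; the
report instead carries the expected number of false positives at the
chosen alpha (``alpha * n_matches``) so a reader can judge the flag counts
against chance.

Determinism: all randomness (Monte-Carlo K-S replicates, kurtosis null
streams) is derived from the single ``seed`` in :class:`BatchConfig` via
``numpy.random.SeedSequence``, so rerunning the same input with the same
config reproduces the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dma_core import double_moving_average, summarize_fluctuation
from .errors import UsageError
from .expected_dist import expected_dma_distribution
from .goodness_of_fit import ks_test
from .kurtosis import KurtosisNullCache, kurtosis_z_test, sample_kurtosis
from .rally_io import MatchRecord

__all__ = ["BatchConfig", "BatchReport", "analyze_matches"]

logger = logging.getLogger(__name__)

_MIN_KURTOSIS_SEGMENT = 20  # valid DMA values needed for the kurtosis null


@dataclass(frozen=True)
class BatchConfig:
    """Knobs of a batch run; the defaults mirror single-match defaults."""

    seed: int = 0
    ks_method: Literal["asymptotic", "monte_carlo"] = "asymptotic"
    mc_replicates: int = 2000
    kurtosis_total_draws: int = 1_000_000
    kurtosis_variant: Literal["adjusted", "moment"] = "adjusted"
    alpha: float = 0.05
    run_ks: bool = True
    run_kurtosis: bool = True


@dataclass(frozen=True)
class BatchReport:
    """Per-match results plus tournament-level aggregates."""

    per_match: pd.DataFrame
    n_matches: int
    n_skipped: int
    prop_ks_significant: float
    prop_kurtosis_significant: float
    expected_false_positives: float
    config_snapshot: dict = field(default_factory=dict)


def analyze_matches(
    records: Sequence[MatchRecord], config: BatchConfig | None = None
) -> BatchReport:
    """Run the full per-match fluctuation analysis over a list of matches.

    Matches shorter than 7 rallies cannot carry a window-4 DMA and are
    skipped with a warning. The kurtosis test additionally needs
    0 < p < 1, at least 20 valid DMA values and a non-constant DMA series;
    matches failing that get NaN kurtosis columns and count as
    non-significant.
    """
    cfg = config or BatchConfig()
    null_cache = KurtosisNullCache(
        master_seed=cfg.seed,
        total_draws=cfg.kurtosis_total_draws,
        variant=cfg.kurtosis_variant,
    )
    rows: list[dict] = []
    n_skipped = 0
    for idx, rec in enumerate(records):
        series = rec.rally_series
        if series.n < 7:
            logger.warning(
                "skipping match %s: %d rallies (< 7 needed for the DMA)",
                rec.match_id, series.n,
            )
            n_skipped += 1
            continue
        dma = double_moving_average(series)
        summ = summarize_fluctuation(dma, series)
        p = summ.wp
        row: dict = {
            "match_id": rec.match_id,
            "n_rallies": series.n,
            "n_valid_dma": dma.n_valid,
            "p": p,
            **dataclasses.asdict(summ),
        }

        if cfg.run_ks:
            expected = expected_dma_distribution(p)
            ks_seed = int(np.random.SeedSequence((cfg.seed, 1, idx)).generate_state(1)[0])
            ks = ks_test(
                dma, expected,
                method=cfg.ks_method,
                mc_replicates=cfg.mc_replicates,
                seed=ks_seed,
            )
            row.update(
                ks_d=ks.d,
                ks_p_value=ks.p_value,
                ks_method=ks.method,
                ks_significant=ks.p_value < cfg.alpha,
            )

        if cfg.run_kurtosis:
            testable = (
                0.0 < p < 1.0
                and dma.n_valid >= _MIN_KURTOSIS_SEGMENT
                and np.ptp(dma.values) > 0
            )
            if testable:
                null = null_cache.get(p, dma.n_valid)
                kt = kurtosis_z_test(dma, null)
                row.update(
                    observed_kurtosis=kt.observed_kurtosis,
                    kurtosis_null_mean=null.null_mean,
                    kurtosis_null_sd=null.null_sd,
                    kurtosis_z=kt.z,
                    kurtosis_p_value=kt.p_two_sided,
                    kurtosis_significant=kt.p_two_sided < cfg.alpha,
                    kurtosis_seed=null.seed,
                )
            else:
                logger.info(
                    "match %s: kurtosis test not defined (p=%.3f, n_valid=%d)",
                    rec.match_id, p, dma.n_valid,
                )
                row.update(
                    observed_kurtosis=np.nan,
                    kurtosis_null_mean=np.nan,
                    kurtosis_null_sd=np.nan,
                    kurtosis_z=np.nan,
                    kurtosis_p_value=np.nan,
                    kurtosis_significant=False,
                    kurtosis_seed=np.nan,
                )
        rows.append(row)

    if not rows:
        raise UsageError("no analyzable matches (all shorter than 7 rallies)")

    per_match = pd.DataFrame(rows)
    n_matches = len(per_match)
    prop_ks = (
        float(per_match["ks_significant"].mean()) if cfg.run_ks else float("nan")
    )
    prop_kurt = (
        float(per_match["kurtosis_significant"].mean())
        if cfg.run_kurtosis
        else float("nan")
    )
    return BatchReport(
        per_match=per_match,
        n_matches=n_matches,
        n_skipped=n_skipped,
        prop_ks_significant=prop_ks,
        prop_kurtosis_significant=prop_kurt,
        expected_false_positives=cfg.alpha * n_matches,
        config_snapshot=dataclasses.asdict(cfg),
    )
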