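"""Seeded generators of rally outcome sequences for testing and calibration.

Three data-generating processes are provided, all emitting
:class:`~rallyflux.rally_io.RallyOutcomeSeries` so that every downstream
stage (DMA, K-S, kurtosis) is exercised end to end:

``iid``
    Independent Bernoulli(p) rallies — the null model under which the
    expected DMA distribution and the kurtosis null are derived.
``markov``
    A stationary two-state Markov chain with marginal winning probability
    ``p`` and lag-1 autocorrelation ``rho``; the operationalisation of
    "streakiness" (outcomes of former rallies pulling later ones the same
    way). Transitions: P(1|1) = p + rho*(1-p), P(1|0) = p*(1-rho); rho = 0
    recovers the iid case exactly.
``regimes``
    Concatenated independent Bernoulli blocks with per-phase winning
    probabilities — the advantageous / stalemate / disadvantageous periods
    of a match, used for power analysis of the fluctuation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import UsageError
from .rally_io import RallyOutcomeSeries

__all__ = [
    "SimulationSpec",
    "generate_iid",
    "generate_markov",
    "generate_regimes",
    "generate",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_iid(
    p: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    perspective: str = "simulated",
) -> RallyOutcomeSeries:
    """n independent Bernoulli(p) rally outcomes."""
    if not 0.0 <= p <= 1.0:
        raise UsageError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise UsageError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    outcomes = (rng.random(n) < p).astype(np.int8)
    return RallyOutcomeSeries(outcomes, perspective=perspective)


def markov_transitions(p: float, rho: float) -> tuple[float, float]:
    """Transition probabilities (P(1|1), P(1|0)) for marginal p, lag-1 rho.

    Valid whenever both values land in [0, 1]; for given p that means
    rho in (-min(p/(1-p), (1-p)/p), 1].
    """
    if not 0.0 < p < 1.0:
        raise UsageError(f"markov generator needs 0 < p < 1, got {p}")
    p11 = p + rho * (1.0 - p)
    p10 = p * (1.0 - rho)
    if not (0.0 <= p11 <= 1.0 and 0.0 <= p10 <= 1.0):
        raise UsageError(
            f"(p={p}, rho={rho}) gives invalid transition probabilities "
            f"P(1|1)={p11:.4f}, P(1|0)={p10:.4f}"
        )
    return p11, p10


def generate_markov(
    p: float,
    rho: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    perspective: str = "simulated",
) -> RallyOutcomeSeries:
    """Stationary two-state Markov rally chain (streaky outcomes).

    The initial state is drawn from the stationary law Bernoulli(p), so the
    whole sequence has marginal winning probability p and lag-1
    autocorrelation rho.
    """
    if n < 1:
        raise UsageError(f"n must be >= 1, got {n}")
    p11, p10 = markov_transitions(p, rho)
    rng = _rng(seed)
    u = rng.random(n)
    x = np.empty(n, dtype=np.int8)
    x[0] = u[0] < p
    for t in range(1, n):
        x[t] = u[t] < (p11 if x[t - 1] else p10)
    return RallyOutcomeSeries(x, perspective=perspective)


def generate_regimes(
    phases: Sequence[tuple[float, int]],
    seed: int | np.random.Generator | None = None,
    perspective: str = "simulated",
) -> RallyOutcomeSeries:
    """Concatenated Bernoulli blocks: phases of differing winning probability.

    ``phases`` is a sequence of ``(p_phase, length)`` pairs.
    """
    if not phases:
        raise UsageError("regimes generator needs at least one phase")
    rng = _rng(seed)
    blocks = []
    for i, (p_phase, length) in enumerate(phases, start=1):
        if not 0.0 <= p_phase <= 1.0:
            raise UsageError(f"phase {i}: p must be in [0, 1], got {p_phase}")
        if length < 1:
            raise UsageError(f"phase {i}: length must be >= 1, got {length}")
        blocks.append((rng.random(length) < p_phase).astype(np.int8))
    return RallyOutcomeSeries(np.concatenate(blocks), perspective=perspective)


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of one simulated rally sequence."""

    kind: Literal["iid", "markov", "regimes"]
    n: int
    p: float = 0.5
    rho: float = 0.0
    phases: tuple[tuple[float, int], ...] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "regimes":
            if not self.phases:
                raise UsageError("regimes spec needs phases")
            total = sum(length for _, length in self.phases)
            if total != self.n:
                raise UsageError(
                    f"phase lengths sum to {total} but n = {self.n}"
                )
        elif self.kind == "markov":
            markov_transitions(self.p, self.rho)  # validate early
        elif self.kind != "iid":
            raise UsageError(f"unknown simulation kind {self.kind!r}")


def generate(spec: SimulationSpec) -> RallyOutcomeSeries:
    """Generate the rally sequence described by ``spec``."""
    if spec.kind == "iid":
        return generate_iid(spec.p, spec.n, seed=spec.seed)
    if spec.kind == "markov":
        return generate_markov(spec.p, spec.rho, spec.n, seed=spec.seed)
    return generate_regimes(list(spec.phases), seed=spec.seed)
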