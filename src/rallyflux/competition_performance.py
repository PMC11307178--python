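"""Improved competition performance (CP): a 0–22 match dominance score.

CP condenses a match's set scores into one number per player, symmetric
between the opponents about 11: the two CP values always sum to 22, with 22
for a player who takes every set 11–0 and 0 for one who loses every set
0–11. The traditional score assigns a set its point margin plus 11, which
gives 11–9, 12–10, 13–11, ... identical credit although the winner's
dominance clearly shrinks along that sequence (a deuce set is nearly even
no matter the final score). The improved per-set score (SCP) removes that
flaw:

* set won at 11 (no deuce):   SCP_winner = 22 - points_loser
  (11-0 -> 22, 11-5 -> 17, 11-9 -> 13);
* deuce set won w:(w-2), w > 11, default exponential decay:
      SCP_winner = 11 + 2 * 1.25^-(w-11)
  (12-10 -> 12.6, 13-11 -> 12.28, ...), strictly decreasing in w and
  approaching the even-set value 11 from above;
* the loser of a set always gets 22 - SCP_winner.

A linear decay variant, SCP_winner = max(11, 13 - 1.25*(w-11)), is provided
for sensitivity checks; it shares the constants and the 11-9 > 12-10 >
13-11 ordering but flattens to 11 from 13-11 onward. The exact algebraic
form printed in the sports-performance literature could not be recovered from its
typography; both variants here are reconstructions constrained to satisfy
every property the accompanying text states (range, extremes, symmetry,
decreasing deuce dominance, and the constants 11, 22 and 1.25) — see
docs/methods.md.

Match CP is the arithmetic mean of the focal player's per-set values. Note
that a match winner's CP can fall below 11 if the sets they won were deuce
sets while those they lost were clear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import UsageError
from .rally_io import FocalSet, SetScore

__all__ = [
    "CPResult",
    "set_cp",
    "match_cp",
    "traditional_set_cp",
]

CPVariant = Literal["exponential", "linear"]


@dataclass(frozen=True)
class CPResult:
    """Per-set and match-level competition performance for both players.

    ``cp_focal`` is the mean of the focal player's per-set values
    (``scp_per_set``); ``cp_opponent = 22 - cp_focal``. ``cp_winner`` /
    ``cp_loser`` re-label the same two numbers by who took more sets (ties
    fall to the focal player).
    """

    scp_per_set: list[float]
    cp_focal: float
    cp_opponent: float
    cp_winner: float
    cp_loser: float
    n_sets: int
    formula_variant: CPVariant
    focal_is_winner: bool


def set_cp(
    set_score: SetScore,
    won_by_focal: bool,
    variant: CPVariant = "exponential",
) -> float:
    """Improved per-set competition performance from the focal perspective.

    Returns the focal player's SCP in [0, 22]; the opponent's value is
    ``22 -`` this one.
    """
    if variant not in ("exponential", "linear"):
        raise UsageError(f"unknown CP variant {variant!r}")
    w, l = set_score.points_winner, set_score.points_loser
    if w == 11:
        s = 22.0 - l
    elif variant == "exponential":
        s = 11.0 + 2.0 * 1.25 ** (-(w - 11))
    else:
        s = max(11.0, 13.0 - 1.25 * (w - 11))
    return s if won_by_focal else 22.0 - s


def traditional_set_cp(set_score: SetScore, won_by_focal: bool) -> float:
    """Equal-margin baseline: 11 plus the focal player's point margin.

    Gives identical credit to 11-9, 12-10, 13-11, ... (margin 2); kept as
    the reference the improved score is measured against.
    """
    margin = set_score.points_winner - set_score.points_loser
    return 11.0 + margin if won_by_focal else 11.0 - margin


def match_cp(
    sets: Sequence[FocalSet],
    variant: CPVariant = "exponential",
) -> CPResult:
    """Match-level CP for the focal player and the opponent.

    ``sets`` is the output of :func:`rallyflux.rally_io.parse_scoreline`
    (or any sequence of :class:`FocalSet`).
    """
    if not sets:
        raise UsageError("match_cp needs at least one set")
    scp = [set_cp(fs.score, fs.won_by_focal, variant) for fs in sets]
    cp_focal = sum(scp) / len(scp)
    cp_opponent = 22.0 - cp_focal
    sets_won = sum(fs.won_by_focal for fs in sets)
    focal_is_winner = 2 * sets_won >= len(sets)
    cp_winner, cp_loser = (
        (cp_focal, cp_opponent) if focal_is_winner else (cp_opponent, cp_focal)
    )
    return CPResult(
        scp_per_set=scp,
        cp_focal=cp_focal,
        cp_opponent=cp_opponent,
        cp_winner=cp_winner,
        cp_loser=cp_loser,
        n_sets=len(sets),
        formula_variant=variant,
        focal_is_winner=focal_is_winner,
    )
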