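"""Reading, writing and parsing of rally sequences, scorelines and results.

The raw material of every analysis in this package is the rally-by-rally
win/loss sequence of one player — a binary time series recorded from the
focal player's perspective (1 = focal player won the rally). This module
defines the containers for that series (:class:`RallyOutcomeSeries`), for
set scores (:class:`SetScore`) and for whole matches (:class:`MatchRecord`),
plus CSV/JSON readers and writers and a scoreline parser.

File conventions
----------------
Rally CSV: one row per rally with columns ``match_id``, ``rally_index``
(1-based, consecutive within a match), ``outcome`` (0 or 1). Column names
can be remapped via the ``columns`` argument so third-party exports can be
ingested without editing the file.

Scorelines: comma-separated ``a:b`` pairs from the focal player's
perspective; ``-`` and the en dash are accepted as separators besides
``:``, and whitespace is ignored, e.g. ``"12:10, 7-11, 11:4"``.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParseError, UsageError

__all__ = [
    "RallyOutcomeSeries",
    "SetScore",
    "FocalSet",
    "MatchRecord",
    "parse_scoreline",
    "read_rally_csv",
    "write_rally_csv",
    "write_results_table",
    "read_results_table",
]


@dataclass(frozen=True)
class RallyOutcomeSeries:
    """Ordered binary rally outcomes from one player's perspective.

    Parameters
    ----------
    outcomes:
        Sequence of 0/1 values, one per rally, in playing order.
    perspective:
        Free-text label of the focal player (default ``"focal"``).
    """

    outcomes: np.ndarray
    perspective: str = "focal"

    def __post_init__(self) -> None:
        arr = np.asarray(self.outcomes)
        if arr.ndim != 1 or arr.size == 0:
            raise InputError("outcomes must be a non-empty 1-D sequence")
        if not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))][0]
            raise InputError(f"outcomes must be 0 or 1, found {bad!r}")
        arr = arr.astype(np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "outcomes", arr)

    @property
    def n(self) -> int:
        """Number of rallies."""
        return int(self.outcomes.size)

    @property
    def wins(self) -> int:
        """Number of rallies won by the focal player."""
        return int(self.outcomes.sum())

    @property
    def wp(self) -> float:
        """Overall point-winning probability (wins / n)."""
        return self.wins / self.n

    def complement(self) -> "RallyOutcomeSeries":
        """The same match seen from the opponent (0 and 1 swapped)."""
        return RallyOutcomeSeries(
            1 - self.outcomes, perspective=f"opponent of {self.perspective}"
        )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass(frozen=True)
class SetScore:
    """Final score of one table-tennis set, winner's points first.

    An 11-point set is won either at 11 with the loser on 0–9 points, or
    beyond 11 ("deuce") with a margin of exactly two.
    """

    points_winner: int
    points_loser: int

    def __post_init__(self) -> None:
        w, l = self.points_winner, self.points_loser
        if w < 11:
            raise InputError(f"set winner must score at least 11, got {w}")
        if l < 0:
            raise InputError(f"loser points must be non-negative, got {l}")
        if w == 11 and not 0 <= l <= 9:
            raise InputError(
                f"a set won 11-{l} is impossible: at 10-10 play continues to a "
                "two-point margin"
            )
        if w > 11 and w - l != 2:
            raise InputError(
                f"a deuce set must be won by exactly two points, got {w}-{l}"
            )

    @property
    def total_points(self) -> int:
        return self.points_winner + self.points_loser

    @property
    def is_deuce(self) -> bool:
        """True if the set went beyond 11 points."""
        return self.points_winner > 11


class FocalSet(NamedTuple):
    """A set score together with whether the focal player won it."""

    score: SetScore
    won_by_focal: bool

    @property
    def points_focal(self) -> int:
        return self.score.points_winner if self.won_by_focal else self.score.points_loser

    @property
    def points_opponent(self) -> int:
        return self.score.points_loser if self.won_by_focal else self.score.points_winner


_PAIR_RE = re.compile(r"^\s*(\d+)\s*[:\-–—]\s*(\d+)\s*$")


def parse_scoreline(text: str) -> list[FocalSet]:
    """Parse a comma-separated scoreline from the focal player's perspective.

    ``"12:10,7:11,11:4"`` means the focal player won set 1 (12-10), lost
    set 2 (7-11) and won set 3 (11-4). Both ``:`` and dash separators are
    accepted. Each set must be a legal 11-point-system score.

    Returns a list of :class:`FocalSet`.
    """
    if not text or not text.strip():
        raise ParseError("empty scoreline")
    sets: list[FocalSet] = []
    for i, token in enumerate(text.split(","), start=1):
        m = _PAIR_RE.match(token)
        if m is None:
            raise ParseError(f"set {i}: cannot parse {token.strip()!r}")
        a, b = int(m.group(1)), int(m.group(2))
        if a == b:
            raise ParseError(f"set {i}: {a}:{b} has no winner")
        try:
            score = SetScore(max(a, b), min(a, b))
        except InputError as exc:
            raise ParseError(f"set {i}: {exc}") from exc
        sets.append(FocalSet(score=score, won_by_focal=a > b))
    return sets


def format_scoreline(sets: Sequence[FocalSet]) -> str:
    """Inverse of :func:`parse_scoreline` (colon-separated form)."""
    return ",".join(f"{fs.points_focal}:{fs.points_opponent}" for fs in sets)


@dataclass
class MatchRecord:
    """One match: its rally series plus optional set scores and metadata."""

    match_id: str
    rally_series: RallyOutcomeSeries
    set_scores: list[FocalSet] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.set_scores is not None:
            total = sum(fs.score.total_points for fs in self.set_scores)
            if total != self.rally_series.n:
                raise InputError(
                    f"match {self.match_id}: set scores total {total} points "
                    f"but the rally series has {self.rally_series.n}"
                )


_DEFAULT_COLUMNS = {
    "match_id": "match_id",
    "rally_index": "rally_index",
    "outcome": "outcome",
}


def read_rally_csv(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[MatchRecord]:
    """Read a rally CSV into one :class:`MatchRecord` per match.

    Parameters
    ----------
    path:
        CSV file with a header row.
    columns:
        Optional remapping of logical names (``match_id``, ``rally_index``,
        ``outcome``) to the file's actual column names.

    Rallies are returned in ascending ``rally_index`` order per match;
    indices must be exactly 1..n with no gaps or duplicates. Matches appear
    in order of first appearance in the file.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise InputError(f"rally CSV is missing columns: {missing}")

    mid, ridx, out = colmap["match_id"], colmap["rally_index"], colmap["outcome"]

    bad = ~df[out].isin((0, 1))
    if bad.any():
        row = int(df.index[bad][0]) + 2  # +2: header line + 1-based
        raise InputError(
            f"non-binary outcome {df.loc[df.index[bad][0], out]!r} at file row {row}"
        )

    records: list[MatchRecord] = []
    for match_id, grp in df.groupby(mid, sort=False):
        grp = grp.sort_values(ridx)
        idx = grp[ridx].to_numpy()
        n = len(idx)
        if len(np.unique(idx)) != n:
            dup = int(idx[pd.Series(idx).duplicated().to_numpy()][0])
            raise InputError(f"match {match_id}: duplicate rally index {dup}")
        if idx[0] != 1 or idx[-1] != n:
            raise InputError(
                f"match {match_id}: rally indices must run 1..{n} without gaps"
            )
        series = RallyOutcomeSeries(grp[out].to_numpy())
        records.append(MatchRecord(match_id=str(match_id), rally_series=series))
    if not records:
        raise InputError(f"no matches found in {path}")
    return records


def write_rally_csv(records: Iterable[MatchRecord], path: str | Path) -> None:
    """Write matches to the standard rally CSV layout (see module docs)."""
    rows = []
    for rec in records:
        for i, x in enumerate(rec.rally_series.outcomes, start=1):
            rows.append({"match_id": rec.match_id, "rally_index": i, "outcome": int(x)})
    pd.DataFrame(rows, columns=["match_id", "rally_index", "outcome"]).to_csv(
        path, index=False
    )


def _flatten(obj: Any) -> dict[str, Any]:
    d = dataclasses.asdict(obj)
    flat: dict[str, Any] = {}
    for k, v in d.items():
        if isinstance(v, (list, tuple, np.ndarray)):
            flat[k] = ";".join(repr(float(x)) for x in np.asarray(v).ravel())
        elif isinstance(v, dict):
            flat[k] = json.dumps(v)
        elif isinstance(v, np.generic):
            flat[k] = v.item()
        else:
            flat[k] = v
    return flat


def write_results_table(results: Sequence[Any], path: str | Path) -> None:
    """Serialize a homogeneous list of result dataclasses to CSV or JSON.

    The output format follows the file suffix (``.json`` → JSON records,
    anything else → CSV). List-valued fields are semicolon-joined in CSV and
    kept as lists in JSON. Floats are written at full precision. An empty
    list produces a file with no data rows.
    """
    path = Path(path)
    types = {type(r) for r in results}
    if len(types) > 1:
        raise UsageError(f"mixed result types cannot share a table: {sorted(t.__name__ for t in types)}")
    if results and not dataclasses.is_dataclass(results[0]):
        raise UsageError(f"results must be dataclasses, got {types.pop().__name__}")
    if path.suffix == ".json":
        payload = [dataclasses.asdict(r) for r in results]
        path.write_text(json.dumps(payload, indent=2, default=float))
        return
    rows = [_flatten(r) for r in results]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=None)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
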