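"""Rally CSV round-trips, scoreline parsing and result serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rallyflux import (
    FluctuationSummary,
    InputError,
    MatchRecord,
    ParseError,
    RallyOutcomeSeries,
    SetScore,
    UsageError,
    parse_scoreline,
    read_rally_csv,
    write_rally_csv,
    write_results_table,
)
from rallyflux.rally_io import format_scoreline, read_results_table


class TestRallyOutcomeSeries:
    def test_basic_construction(self):
        s = RallyOutcomeSeries([1, 0, 1], perspective="winner")
        assert s.n == 3
        assert s.wins == 2
        assert s.wp == pytest.approx(2 / 3)

    @pytest.mark.parametrize("bad", [[1, 2, 0], [0.5, 1], [], [[1, 0]]])
    def test_rejects_non_binary_or_empty(self, bad):
        with pytest.raises(InputError):
            RallyOutcomeSeries(bad)

    def test_complement_swaps_outcomes(self):
        s = RallyOutcomeSeries([1, 0, 1, 1])
        assert np.array_equal(s.complement().outcomes, [0, 1, 0, 0])


class TestSetScore:
    @pytest.mark.parametrize("w,l", [(11, 0), (11, 9), (12, 10), (15, 13), (25, 23)])
    def test_valid_scores(self, w, l):
        assert SetScore(w, l).points_winner == w

    @pytest.mark.parametrize("w,l", [(11, 10), (10, 8), (12, 9), (11, -1), (13, 12), (9, 11)])
    def test_invalid_scores(self, w, l):
        with pytest.raises(InputError):
            SetScore(w, l)


class TestParseScoreline:
    def test_seven_set_deuce_heavy_match(self):
        # a published 4-3 match scoreline with three deuce sets
        sets = parse_scoreline("12:10,7:11,7:11,5:11,13:11,11:4,11:8")
        assert len(sets) == 7
        assert [fs.won_by_focal for fs in sets] == [
            True, False, False, False, True, True, True,
        ]
        assert sum(fs.won_by_focal for fs in sets) == 4
        assert sets[4].score == SetScore(13, 11)

    def test_single_set(self):
        (fs,) = parse_scoreline("11:0")
        assert fs.score == SetScore(11, 0) and fs.won_by_focal

    @pytest.mark.parametrize("text", ["11:10", "10:8", "11:11", "", "7;11", "12:10,,11:4"])
    def test_rejects_malformed(self, text):
        with pytest.raises(ParseError):
            parse_scoreline(text)

    def test_dash_separators_and_whitespace(self):
        sets = parse_scoreline(" 12-10 , 7–11 , 11:4 ")
        assert [fs.points_focal for fs in sets] == [12, 7, 11]
        assert [fs.won_by_focal for fs in sets] == [True, False, True]

    def test_error_names_the_offending_set(self):
        with pytest.raises(ParseError, match="set 2"):
            parse_scoreline("11:5,11:10")


def _valid_set_strategy():
    regular = st.integers(0, 9).map(lambda l: (11, l))
    deuce = st.integers(12, 30).map(lambda w: (w, w - 2))
    return st.one_of(regular, deuce)


class TestScorelineProperty:
    @given(st.lists(st.tuples(_valid_set_strategy(), st.booleans()), min_size=1, max_size=7))
    def test_roundtrip_of_valid_scorelines(self, described):
        text = ",".join(
            f"{w}:{l}" if won else f"{l}:{w}" for (w, l), won in described
        )
        sets = parse_scoreline(text)
        assert [(fs.score.points_winner, fs.score.points_loser) for fs in sets] == [
            s for s, _ in described
        ]
        assert [fs.won_by_focal for fs in sets] == [won for _, won in described]
        assert parse_scoreline(format_scoreline(sets)) == sets

    @given(
        st.integers(0, 30), st.integers(0, 30),
        st.lists(st.tuples(_valid_set_strategy(), st.booleans()), max_size=3),
    )
    def test_invalid_set_anywhere_is_rejected(self, a, b, valid_tail):
        w, l = max(a, b), min(a, b)
        is_valid = (w == 11 and 0 <= l <= 9) or (w > 11 and w - l == 2)
        tail = ",".join(f"{w2}:{l2}" if won else f"{l2}:{w2}" for (w2, l2), won in valid_tail)
        text = f"{a}:{b}" + ("," + tail if tail else "")
        if is_valid:
            parse_scoreline(text)
        else:
            with pytest.raises(ParseError):
                parse_scoreline(text)


class TestRallyCsv:
    def test_single_match(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text("match_id,rally_index,outcome\nm1,1,1\nm1,2,0\nm1,3,1\n")
        (rec,) = read_rally_csv(f)
        assert rec.match_id == "m1"
        assert np.array_equal(rec.rally_series.outcomes, [1, 0, 1])

    def test_interleaved_matches_roundtrip(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text(
            "match_id,rally_index,outcome\n"
            "a,1,1\nb,1,0\na,2,0\nb,2,1\na,3,1\nb,3,1\n"
        )
        recs = read_rally_csv(f)
        assert [r.match_id for r in recs] == ["a", "b"]
        assert np.array_equal(recs[0].rally_series.outcomes, [1, 0, 1])
        assert np.array_equal(recs[1].rally_series.outcomes, [0, 1, 1])
        out = tmp_path / "out.csv"
        write_rally_csv(recs, out)
        again = read_rally_csv(out)
        for r1, r2 in zip(recs, again):
            assert r1.match_id == r2.match_id
            assert np.array_equal(r1.rally_series.outcomes, r2.rally_series.outcomes)

    def test_non_binary_outcome_names_row(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text("match_id,rally_index,outcome\nm1,1,1\nm1,2,2\n")
        with pytest.raises(InputError, match="row 3"):
            read_rally_csv(f)

    @pytest.mark.parametrize(
        "rows,msg",
        [("m1,1,1\nm1,1,0", "duplicate"), ("m1,1,1\nm1,3,0", "gaps")],
    )
    def test_bad_rally_indices(self, tmp_path, rows, msg):
        f = tmp_path / "r.csv"
        f.write_text(f"match_id,rally_index,outcome\n{rows}\n")
        with pytest.raises(InputError, match=msg):
            read_rally_csv(f)

    def test_column_remapping(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text("game,pt,won\nm1,1,1\nm1,2,0\n")
        (rec,) = read_rally_csv(
            f, columns={"match_id": "game", "rally_index": "pt", "outcome": "won"}
        )
        assert np.array_equal(rec.rally_series.outcomes, [1, 0])


class TestMatchRecord:
    def test_set_points_must_match_rally_count(self):
        series = RallyOutcomeSeries([1] * 11)
        sets = parse_scoreline("11:0")
        MatchRecord("m", series, set_scores=sets)  # 11 points, 11 rallies: ok
        with pytest.raises(InputError, match="set scores total"):
            MatchRecord("m", RallyOutcomeSeries([1] * 10), set_scores=sets)


class TestResultsTable:
    def _summaries(self):
        return [
            FluctuationSummary(0.5, 0.1, 0.2, 0.2, True, False, 94, 0.55),
            FluctuationSummary(0.6, 0.15, 0.25, 0.25, False, False, 50, 0.6),
        ]

    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_roundtrip(self, tmp_path, suffix):
        path = tmp_path / f"res{suffix}"
        write_results_table(self._summaries(), path)
        df = read_results_table(path)
        assert len(df) == 2
        assert df["mean_dma"].tolist() == pytest.approx([0.5, 0.6])
        assert df["n_valid"].tolist() == [94, 50]

    def test_empty_list_gives_no_data_rows(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_results_table([], path)
        assert len(read_results_table(path)) == 0

    def test_mixed_types_rejected(self, tmp_path):
        rows = self._summaries() + [SetScore(11, 0)]
        with pytest.raises(UsageError):
            write_results_table(rows, tmp_path / "bad.csv")
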