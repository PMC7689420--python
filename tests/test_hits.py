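"""Classification, scoring, ranking and annotation-table assembly."""

import math
import random

import pytest

from volcanokit.errors import ForeignRecordError
from volcanokit.hits import (
    RankingSpec,
    Thresholds,
    classify,
    classify_data,
    merge_annotations,
    score,
    select_by_name,
    top_hits,
)
from volcanokit.io import VolcanoData, VolcanoRecord

T = Thresholds(-1.5, 1.5, 2.0)


def rec(x, y, name="r"):
    return VolcanoRecord(name, x, y)


def random_data(rng, n=100, scale=5.0):
    records = [
        rec(rng.uniform(-scale, scale), rng.uniform(0, scale), f"g{i}")
        for i in range(n)
    ]
    return VolcanoData(records, "fc", "mlogp")


class TestClassify:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (2.0, 3.0, "increased"),
            (-2.0, 3.0, "decreased"),
            (0.0, 3.0, "unchanged"),
            (2.0, 1.0, "unchanged"),
            # points exactly on a threshold line are unchanged
            (1.5, 3.0, "unchanged"),
            (-1.5, 3.0, "unchanged"),
            (2.0, 2.0, "unchanged"),
        ],
    )
    def test_three_way_rule_with_strict_boundaries(self, x, y, expected):
        assert classify(rec(x, y), T) == expected

    def test_partition_of_random_points(self):
        rng = random.Random(7)
        data = classify_data(random_data(rng, 1000), T)
        counts = {"unchanged": 0, "increased": 0, "decreased": 0}
        for r in data.records:
            counts[r.category] += 1
            # category is consistent with the defining inequalities
            if r.category == "increased":
                assert r.x > T.fc_high and r.y > T.sig
            elif r.category == "decreased":
                assert r.x < T.fc_low and r.y > T.sig
            else:
                assert not (r.x > T.fc_high and r.y > T.sig)
                assert not (r.x < T.fc_low and r.y > T.sig)
        assert sum(counts.values()) == 1000

    def test_symmetric_constructor_expands_scalar(self):
        t = Thresholds.symmetric(3, 1)
        assert (t.fc_low, t.fc_high, t.sig) == (-3, 3, 1)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(2.0, -2.0, 1.0)


class TestScore:
    @pytest.mark.parametrize(
        "x,y,criterion,expected",
        [
            (3, 4, "manhattan", 7),
            (3, 4, "euclidean", 5),
            (-3, 4, "manhattan", 7),
            (-3, 4, "fold_change", 3),
            (-3, 4, "significance", 4),
            (-3, -1, "significance", -1),  # malformed negative y ranks last
        ],
    )
    def test_criterion_formulas(self, x, y, criterion, expected):
        assert score(rec(x, y), criterion) == pytest.approx(expected)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            score(rec(1, 1), "cosine")


def brute_force_top(data, t, spec):
    """Independent oracle: score everything, full stable sort, take prefix."""
    classify_data(data, t)
    wanted = (
        {"increased", "decreased"}
        if spec.direction == "significant"
        else {spec.direction}
    )
    scored = [
        (i, r, score(r, spec.criterion))
        for i, r in enumerate(data.records)
        if r.category in wanted
    ]
    scored.sort(key=lambda item: (-item[2], item[0]))
    return [(r.name, s) for _, r, s in scored[: spec.n_top]]


class TestTopHits:
    @pytest.mark.parametrize(
        "criterion", ["manhattan", "euclidean", "fold_change", "significance"]
    )
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, criterion, seed):
        rng = random.Random(seed)
        data = random_data(rng, 100)
        spec = RankingSpec(criterion=criterion, direction="significant", n_top=10)
        table = top_hits(data, T, spec)
        got = [(e.record.name, e.score) for e in table.entries]
        assert got == brute_force_top(data, T, spec)

    def test_scores_non_increasing_and_ranks_sequential(self):
        rng = random.Random(3)
        table = top_hits(random_data(rng, 200), T, RankingSpec(n_top=10))
        scores = [e.score for e in table.entries]
        assert scores == sorted(scores, reverse=True)
        assert [e.rank for e in table.entries] == list(
            range(1, len(table.entries) + 1)
        )
        assert all(e.origin == "ranked" for e in table.entries)

    def test_direction_filter_soundness(self):
        rng = random.Random(5)
        data = random_data(rng, 300)
        for direction, allowed in [
            ("increased", {"increased"}),
            ("decreased", {"decreased"}),
            ("significant", {"increased", "decreased"}),
        ]:
            table = top_hits(data, T, RankingSpec(direction=direction, n_top=50))
            assert {e.record.category for e in table.entries} <= allowed

    def test_empty_eligible_set_yields_empty_table(self):
        data = VolcanoData([rec(-3.0, 5.0, "down")], "fc", "p")
        table = top_hits(data, T, RankingSpec(direction="increased"))
        assert len(table) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_n_top_nesting(self, seed):
        rng = random.Random(seed)
        data = random_data(rng, 150)
        names = {
            k: top_hits(
                data, T, RankingSpec(direction="significant", n_top=k)
            ).names
            for k in range(0, 12)
        }
        for k in range(11):
            assert names[k] == names[k + 1][: len(names[k])]

    def test_scale_invariance_of_distance_rankings(self):
        rng = random.Random(11)
        data = random_data(rng, 120)
        for criterion in ("manhattan", "euclidean"):
            base = top_hits(
                data, T, RankingSpec(criterion, "significant", 15)
            ).names
            scaled = VolcanoData(
                [rec(3 * r.x, 3 * r.y, r.name) for r in data.records], "fc", "p"
            )
            t3 = Thresholds(3 * T.fc_low, 3 * T.fc_high, 3 * T.sig)
            assert (
                top_hits(scaled, t3, RankingSpec(criterion, "significant", 15)).names
                == base
            )

    def test_stable_tie_break_by_input_order(self):
        data = VolcanoData(
            [rec(2.0, 3.0, "first"), rec(2.5, 2.5, "second"), rec(2.0, 3.0, "third")],
            "fc",
            "p",
        )
        table = top_hits(data, T, RankingSpec("manhattan", "increased", 3))
        assert table.names == ["first", "second", "third"]


class TestSelectByName:
    def data(self):
        return VolcanoData(
            [rec(2, 3, "GNAS"), rec(1, 1, "TP53"), rec(0, 0, "gnas ")],
            "fc",
            "p",
        )

    def test_exact_match(self):
        found = select_by_name(self.data(), ["TP53"])
        assert [r.name for r in found] == ["TP53"]

    def test_case_folded_and_trimmed_match_returns_all_duplicates(self):
        found = select_by_name(self.data(), ["gnas"])
        assert [r.name for r in found] == ["GNAS", "gnas "]

    def test_unmatched_query_warns_not_errors(self):
        with pytest.warns(UserWarning, match="not_present"):
            found = select_by_name(self.data(), ["NOT_PRESENT"])
        assert found == []


class TestMergeAnnotations:
    def setup_method(self):
        rng = random.Random(2)
        self.data = random_data(rng, 200)
        self.table = top_hits(
            self.data, T, RankingSpec(direction="significant", n_top=10)
        )

    def test_manual_only_entries_appended_after_ranked(self):
        ranked_names = set(self.table.names)
        extra = next(
            r for r in self.data.records if r.name not in ranked_names
        )
        merged = merge_annotations(self.table, [extra])
        assert len(merged) == 11
        assert merged.entries[-1].origin == "manual"
        assert merged.entries[-1].rank is None

    def test_already_ranked_record_not_duplicated(self):
        third = self.table.entries[2].record
        merged = merge_annotations(self.table, [third])
        assert len(merged) == 10
        assert merged.entries[2].origin == "ranked"

    def test_manual_only_table(self):
        empty = top_hits(self.data, T, RankingSpec(n_top=0))
        merged = merge_annotations(empty, self.data.records[:2])
        assert len(merged) == 2
        assert {e.origin for e in merged.entries} == {"manual"}

    def test_foreign_record_rejected(self):
        with pytest.raises(ForeignRecordError):
            merge_annotations(self.table, [rec(99.0, 99.0, "alien")])

    def test_csv_export_columns(self, tmp_path):
        out = tmp_path / "hits.csv"
        self.table.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "name,x,y,category,score,rank,origin"
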