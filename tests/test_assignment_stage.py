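"""Stage-2 assignment: candidate tables, exponential weighting, path
chaining/selection, verification, and the two-round composition."""

import math

import numpy as np
import pytest

from metalign import (
    AlignParams,
    Genome,
    build_index,
    build_paths,
    build_tables,
    random_genome,
    select_paths,
    weight_score,
)
from metalign.assignment_stage import (
    Path,
    PositionTable,
    ScoredPosition,
    assignment_round,
    verify_paths,
)
from metalign.core_index import Read


class TestWeightScore:
    def test_printed_formula_values(self):
        assert weight_score(10, 2) == pytest.approx(10 * math.exp(-1.0))
        assert weight_score(10, 2) == pytest.approx(3.6788, abs=1e-4)
        assert weight_score(1, 1) == pytest.approx(0.6065, abs=1e-4)
        assert weight_score(0, 7) == 0.0

    def test_strictly_decreasing_in_table_size_and_nonnegative(self):
        vals = [weight_score(5.0, t) for t in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            weight_score(1.0, 0)


class TestBuildTables:
    def test_unique_region_gives_singleton_tables_at_truth(self, clean_genome):
        start = 4000
        read = Read("r", clean_genome.sequence[start : start + 300])
        index = build_index(clean_genome, 25, 2)
        tables = build_tables(read, index, l=25, step=12, d=2, cap=10)
        assert len(tables) == len(range(0, 300 - 25 + 1, 12))
        for t in tables:
            assert len(t.entries) == 1
            assert t.entries[0].implied_start == start
            assert t.entries[0].raw_score == 25  # exact fragment, match=1

    def test_three_copy_repeat_gives_tables_of_size_three(self):
        flank = random_genome(800, seed=30).sequence
        unit = random_genome(500, seed=31).sequence
        g = Genome("rep3", flank + unit * 3 + flank[::-1])
        read = Read("r", unit[100:350])
        index = build_index(g, 25, 0)
        tables = build_tables(read, index, l=25, step=12, d=0, cap=10)
        assert tables
        assert all(len(t.entries) == 3 for t in tables)

    def test_high_copy_repeat_discards_all_fragments(self):
        unit = random_genome(60, seed=32).sequence
        g = Genome("rep100", unit * 100)
        read = Read("r", unit * 2)
        index = build_index(g, 25, 0)
        assert build_tables(read, index, l=25, step=12, d=0, cap=10) == []

    def test_weighted_scores_follow_table_size(self, clean_genome):
        read = Read("r", clean_genome.sequence[100:400])
        index = build_index(clean_genome, 25, 2)
        tables = build_tables(read, index, l=25, step=25, d=2, cap=10)
        e = tables[0].entries[0]
        assert e.weighted_score == pytest.approx(weight_score(e.raw_score, 1))


def sp(implied, offset, score=10.0, strand="+", frag=0):
    return ScoredPosition(implied, strand, score, score, frag, offset)


class TestBuildPaths:
    def params(self):
        return AlignParams(confirm_slack_rate=0.05, confirm_delta_min=3)

    def test_two_confirming_entries_make_one_path(self):
        tables = [
            PositionTable(0, 0, [sp(1000, 0)]),
            PositionTable(1, 12, [sp(1001, 12, frag=1)]),
        ]
        paths = build_paths(tables, self.params())
        assert len(paths) == 1 and len(paths[0].members) == 2
        assert paths[0].score == pytest.approx(20.0)

    def test_isolated_entry_joins_no_path(self):
        tables = [
            PositionTable(0, 0, [sp(1000, 0)]),
            PositionTable(1, 12, [sp(1001, 12, frag=1), sp(50_000, 12, frag=1)]),
        ]
        paths = build_paths(tables, self.params())
        assert len(paths) == 1
        assert all(m.implied_start != 50_000 for m in paths[0].members)

    def test_two_repeat_copies_give_two_symmetric_paths(self):
        tables = [
            PositionTable(i, i * 12, [sp(1000, i * 12, frag=i), sp(9000, i * 12, frag=i)])
            for i in range(3)
        ]
        paths = build_paths(tables, self.params())
        assert len(paths) == 2
        assert paths[0].score == pytest.approx(paths[1].score)
        assert {p.consensus for p in paths} == {1000, 9000}

    def test_paths_partition_consumed_positions(self):
        tables = [
            PositionTable(i, i * 12, [sp(1000 + i, i * 12, frag=i), sp(7000, i * 12, frag=i)])
            for i in range(4)
        ]
        paths = build_paths(tables, self.params())
        seen = set()
        for p in paths:
            for m in p.members:
                key = id(m)
                assert key not in seen
                seen.add(key)


class TestSelectPaths:
    def mk(self, scores):
        return [Path([sp(0, 0)], s, 0, "+") for s in scores]

    def test_threshold_keeps_relative_high_scores(self):
        kept = select_paths(self.mk([100, 95, 20]), 0.8)
        assert [p.score for p in kept] == [100, 95]

    def test_single_path_always_kept(self):
        assert len(select_paths(self.mk([7]), 1.0)) == 1

    def test_equal_scores_all_kept(self):
        assert len(select_paths(self.mk([5, 5, 5]), 1.0)) == 3

    def test_no_paths_empty_shortlist(self):
        assert select_paths([], 0.8) == []


class TestVerifyPaths:
    def test_true_site_survives_decoy_dropped(self, clean_genome):
        start = 20_000
        read = Read("r", clean_genome.sequence[start : start + 400])
        true_path = Path([sp(start, 0)], 10.0, start, "+")
        decoy_path = Path([sp(70_000, 0)], 9.0, 70_000, "+")
        params = AlignParams(ncd=0.1)
        recs = verify_paths(read, [true_path, decoy_path], clean_genome, params, "stage2-round1")
        assert len(recs) == 1
        assert recs[0].pos == start and not recs[0].is_secondary

    def test_empty_shortlist_reports_nothing(self, clean_genome):
        read = Read("r", clean_genome.sequence[:100])
        assert verify_paths(read, [], clean_genome, AlignParams(), "s") == []


class TestAssignmentRound:
    def test_unique_reads_fully_reported_in_round_one(self, clean_genome):
        reads = [
            Read(f"r{i}", clean_genome.sequence[i * 2000 : i * 2000 + 400])
            for i in range(10)
        ]
        index = build_index(clean_genome, 25, 2)
        params = AlignParams()
        reported, remaining = assignment_round(
            reads, index, clean_genome, 25, 12, 2, 10, params, "stage2-round1"
        )
        assert len(reported) == 10 and remaining == []
        for i, read in enumerate(reads):
            best = reported[read.id][0]
            assert best.pos == i * 2000 and not best.is_secondary

    def test_moderate_copy_repeat_rescued_only_by_larger_cap(self):
        flank = random_genome(2000, seed=33).sequence
        unit = random_genome(400, seed=34).sequence
        g = Genome("rep15", flank + unit * 15 + random_genome(2000, seed=35).sequence)
        read = Read("r", (unit * 2)[50 : 50 + 300])
        params = AlignParams(l1=25, l2=50)
        idx1 = build_index(g, 25, 0)
        rep1, rem1 = assignment_round(
            [read], idx1, g, 25, 12, 0, params.list_cap_1, params, "stage2-round1"
        )
        assert rep1 == {} and rem1 == [read]  # 15 copies > cap 10
        idx2 = build_index(g, 50, 0)
        rep2, rem2 = assignment_round(
            rem1, idx2, g, 50, 25, 0, params.list_cap_2, params, "stage2-round2"
        )
        assert read.id in rep2 and rem2 == []
        positions = {r.pos for r in rep2[read.id]}
        # the true copy (any of the 15 identical ones) is in the list
        assert any(abs(p - (2000 + 50)) % 400 < 5 for p in positions)

    def test_beyond_second_cap_stays_unreported(self):
        unit = random_genome(300, seed=36).sequence
        g = Genome("rep60", unit * 60)
        read = Read("r", (unit * 2)[10 : 10 + 300])
        params = AlignParams()
        idx2 = build_index(g, 50, 0)
        rep, rem = assignment_round(
            [read], idx2, g, 50, 25, 0, params.list_cap_2, params, "stage2-round2"
        )
        assert rep == {} and rem == [read]
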