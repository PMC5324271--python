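"""Stage-1 anchoring: fragmentation, the confirm rule, progressive
anchoring, and the banded local-alignment step."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helpers
from metalign import (
    AlignParams,
    ErrorModel,
    Genome,
    build_index,
    confirms,
    fragment_read,
    local_align,
    random_genome,
    simulate_reads,
)
from metalign.alignment_stage import (
    AMBIGUOUS,
    ANCHORED,
    Tag,
    UNANCHORED,
    _anchor_single_pass,
    anchor_reads,
)
from metalign.core_index import Read


def mk_tag(offset, implied, strand="+"):
    return Tag(
        fragment_index=offset // 25,
        read_offset=offset,
        ref_pos=implied + offset if strand == "+" else 0,
        strand=strand,
        mismatches=0,
        implied_start=implied,
    )


class TestFragmentation:
    def test_kilobase_read_gives_forty_fragments(self):
        read = Read("r", "A" * 1000)
        assert fragment_read(read, 25) == [25 * k for k in range(40)]

    def test_trailing_bases_unused(self):
        assert len(fragment_read(Read("r", "A" * 110), 25)) == 4

    def test_slide_offset_shifts_grid(self):
        offs = fragment_read(Read("r", "A" * 1000), 25, slide_offset=5)
        assert len(offs) == 39 and offs[0] == 5

    def test_short_read_yields_no_fragments(self):
        assert fragment_read(Read("r", "ACGT"), 25) == []


class TestConfirmRule:
    def params(self, rate=0.05, dmin=3):
        return AlignParams(confirm_slack_rate=rate, confirm_delta_min=dmin)

    def test_nearby_same_strand_positions_confirm(self):
        p = self.params()  # span 100 -> window max(3, 5) = 5
        assert confirms(mk_tag(0, 10000), mk_tag(100, 10002), p)

    def test_distant_positions_do_not_confirm(self):
        p = self.params()
        assert not confirms(mk_tag(0, 10000), mk_tag(100, 10100), p)

    def test_opposite_strands_never_confirm(self):
        p = self.params()
        assert not confirms(mk_tag(0, 10000), mk_tag(100, 10000, "-"), p)

    def test_minimum_window_applies_at_small_span(self):
        p = self.params(rate=0.05, dmin=3)  # span 25 -> window 3
        assert confirms(mk_tag(0, 10000), mk_tag(25, 10003), p)
        assert not confirms(mk_tag(0, 10000), mk_tag(25, 10004), p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        o1=st.integers(0, 900), o2=st.integers(0, 900),
        i1=st.integers(0, 10**6), i2=st.integers(0, 10**6),
    )
    def test_confirm_is_symmetric(self, o1, o2, i1, i2):
        p = self.params()
        a, b = mk_tag(o1, i1), mk_tag(o2, i2)
        assert confirms(a, b, p) == confirms(b, a, p)


class TestAnchoring:
    def test_clean_reads_anchor_at_truth_with_two_queries(self, clean_genome):
        reads, truth = simulate_reads(clean_genome, 100, 1000, ErrorModel(), seed=20)
        params = AlignParams(l1=25, d1=2)
        index = build_index(clean_genome, 25, 2)
        index.reset_counters()
        results, remaining = anchor_reads(reads, index, params)
        assert remaining == []
        for t in reads:
            assert results[t.id].status == ANCHORED
        for t, tr in zip(reads, truth):
            assert results[t.id].implied_start == tr.start
            assert results[t.id].strand == tr.strand
        # efficiency contract: an immediately-confirmed read costs 2 queries
        assert index.n_queries == 2 * len(reads)

    def test_read_inside_exact_duplication_stays_unanchored(self):
        s = random_genome(2000, seed=21).sequence
        g = Genome("dup", s + s)
        read = Read("r", s[500:1500])  # wholly inside both copies
        params = AlignParams(l1=25, d1=0)
        index = build_index(g, 25, 0)
        results, remaining = anchor_reads([read], index, params)
        assert results["r"].status == UNANCHORED
        assert remaining == [read]

    def test_decoy_first_fragment_outvoted_by_confirming_pair(self):
        g = random_genome(50_000, seed=22)
        true_start = 10_000
        read_seq = list(g.sequence[true_start : true_start + 1000])
        # make fragment 1 map uniquely to an unrelated locus
        read_seq[0:25] = g.sequence[30_000:30_025]
        read = Read("r", "".join(read_seq))
        params = AlignParams(l1=25, d1=0)
        index = build_index(g, 25, 0)
        results, _ = anchor_reads([read], index, params)
        res = results["r"]
        assert res.status == ANCHORED
        assert res.implied_start == true_start
        assert res.confirming_pair == (1, 2)

    def test_inconsistent_confirmations_marked_ambiguous(self):
        g = random_genome(3000, seed=23)
        s = g.sequence
        # fragments at read offsets 0 / 50 / 75 imply starts 1000 / 1200 /
        # 1150; with slack window 3 + ceil(3*span): f4 confirms both f1 and
        # f3, but f1 and f3 disagree -> ambiguous
        read = Read("r", s[1000:1025] + "N" * 25 + s[1250:1275] + s[1225:1250])
        params = AlignParams(l1=25, d1=0, confirm_slack_rate=3.0)
        index = build_index(g, 25, 0)
        res = _anchor_single_pass(read, index, params, 0)
        assert res.status == AMBIGUOUS
        results, remaining = anchor_reads([read], index, params)
        assert results["r"].status == AMBIGUOUS and remaining == [read]

    def test_sliding_rescues_noisy_short_phase(self, clean_genome):
        # errors planted on the non-slid fragment grid boundaries
        model = ErrorModel(eps=0.12, mismatch_fraction=0.0)
        reads, truth = simulate_reads(clean_genome, 150, 600, model, seed=24)
        index = build_index(clean_genome, 25, 2)
        no_slide = AlignParams(l1=25, d1=2, slide=0, confirm_slack_rate=0.3)
        slide = AlignParams(l1=25, d1=2, slide=5, confirm_slack_rate=0.3)
        r0, rem0 = anchor_reads(reads, index, no_slide)
        r1, rem1 = anchor_reads(reads, index, slide)
        n0 = sum(1 for r in r0.values() if r.status == ANCHORED)
        n1 = sum(1 for r in r1.values() if r.status == ANCHORED)
        assert n1 >= n0
        assert len(rem1) <= len(rem0)

    def test_partition_of_verdicts(self, clean_genome):
        model = ErrorModel(eps=0.15, mismatch_fraction=0.2)
        reads, _ = simulate_reads(clean_genome, 60, 400, model, seed=25)
        index = build_index(clean_genome, 25, 2)
        results, remaining = anchor_reads(reads, index, AlignParams())
        statuses = {rid: r.status for rid, r in results.items()}
        anchored = {rid for rid, s in statuses.items() if s == ANCHORED}
        rem_ids = {r.id for r in remaining}
        assert anchored | rem_ids == {r.id for r in reads}
        assert anchored & rem_ids == set()


class TestLocalAlign:
    def test_exact_read_scores_full_matches(self, clean_genome):
        read = Read("r", clean_genome.sequence[100:300])
        rec = local_align(read, clean_genome, 100, "+", ncd=0.1)
        assert rec.score == 200
        assert rec.cigar == "200M"
        assert rec.pos == 100

    def test_single_substitution_costs_match_plus_penalty(self, clean_genome):
        seq = list(clean_genome.sequence[100:300])
        seq[100] = "ACGT"[("ACGT".index(seq[100]) + 1) % 4]
        rec = local_align(Read("r", "".join(seq)), clean_genome, 100, "+", ncd=0.1)
        assert rec.score == 198  # 199 matches - 1 mismatch

    def test_reverse_strand_alignment(self, clean_genome):
        from metalign.core_index import revcomp

        read = Read("r", revcomp(clean_genome.sequence[500:700]))
        rec = local_align(read, clean_genome, 500, "-", ncd=0.1)
        assert rec.pos == 500 and rec.score == 200 and rec.strand == "-"

    def test_window_clipped_at_genome_bounds(self, clean_genome):
        read = Read("r", clean_genome.sequence[0:200])
        rec = local_align(read, clean_genome, 0, "+", ncd=0.5)
        assert rec.pos == 0 and rec.score == 200

    @pytest.mark.parametrize("eps_g", [0.05, 0.10])
    def test_banded_equals_unbanded_oracle(self, eps_g):
        genome = random_genome(5000, seed=26)
        model = ErrorModel(eps=eps_g + 0.02, mismatch_fraction=0.02 / (eps_g + 0.02))
        reads, truth = simulate_reads(genome, 8, 300, model, seed=27)
        ncd = 5 * eps_g
        import math

        for read, t in zip(reads, truth):
            L = read.length
            pad = math.ceil(ncd * L / 2)
            ws = max(0, t.start - pad)
            we = min(genome.length, t.start + L + pad)
            window = genome.codes[ws:we]
            q = read.codes if t.strand == "+" else helpers.rc(read.codes)
            expect = helpers.full_sw_score(q, window, 1, -1, -1)
            rec = local_align(read, genome, t.start, t.strand, ncd)
            assert rec is not None and rec.score == expect
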