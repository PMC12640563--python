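"""Multimapping trimming: CIGAR rewriting, chain disjointness, idempotence."""

import pytest
from hypothesis import given, strategies as st

from chromwalk.alignments import MateChain, cigar_query_length
from chromwalk.simulate import SimConfig, simulate, iter_sam_records
from chromwalk.alignments import group_pairs
from chromwalk.trim import AdjacentPair, find_adjacent_pairs, trim_chain, trim_overlap

from helpers import make_segment


class TestAdjacentPairs:
    def test_motif_induced_overlap(self):
        chain = MateChain(
            "R1",
            [
                make_segment(read_start=0, read_end=54),
                make_segment(ref_start=5000, read_start=50, read_end=100),
            ],
        )
        (pair,) = find_adjacent_pairs(chain)
        assert pair.overlap_len == 4
        assert pair.gap_len == 0

    def test_abutting_no_overlap(self):
        chain = MateChain(
            "R1",
            [
                make_segment(read_start=0, read_end=50),
                make_segment(ref_start=5000, read_start=50, read_end=100),
            ],
        )
        (pair,) = find_adjacent_pairs(chain)
        assert pair.overlap_len == 0 and pair.gap_len == 0

    def test_single_segment_chain(self):
        chain = MateChain("R1", [make_segment()])
        assert find_adjacent_pairs(chain) == []

    def test_overlap_and_gap_exclusive(self):
        chain = MateChain(
            "R1",
            [
                make_segment(read_start=0, read_end=40),
                make_segment(ref_start=5000, read_start=60, read_end=100),
            ],
        )
        (pair,) = find_adjacent_pairs(chain)
        assert pair.overlap_len == 0 and pair.gap_len == 20


class TestTrimOverlap:
    def test_plus_strand_trims_reference_right(self):
        up = make_segment(ref_start=1000, read_start=0, read_end=54, cigar=[("M", 54), ("S", 46)])
        down = make_segment(ref_start=5000, read_start=50, read_end=100)
        new_up, new_down = trim_overlap(AdjacentPair(up, down))
        assert new_up.cigar == [("M", 50), ("S", 50)]
        assert (new_up.ref_start, new_up.ref_end) == (1000, 1050)
        assert new_up.read_end == 50
        assert new_down.read_start == 54

    def test_minus_strand_downstream_trims_reference_right(self):
        # a minus-strand downstream segment's 5'-in-read end is the
        # reference-right end, so its ref_end shrinks
        up = make_segment(read_start=0, read_end=54)
        down = make_segment(
            ref_start=2000, strand="-", read_start=50, read_end=100,
            cigar=[("M", 50), ("S", 50)],
        )
        _, new_down = trim_overlap(AdjacentPair(up, down))
        assert new_down.cigar == [("M", 46), ("S", 54)]
        assert (new_down.ref_start, new_down.ref_end) == (2000, 2046)
        assert new_down.read_start == 54

    def test_overlap_spanning_insertion(self):
        # removing 4 query bases that include a 2I op shrinks the reference
        # span by only the 2 M bases
        up = make_segment(
            ref_start=1000, ref_end=1052, read_start=0, read_end=54,
            cigar=[("M", 50), ("I", 2), ("M", 2), ("S", 46)],
        )
        down = make_segment(ref_start=5000, read_start=50, read_end=100)
        new_up, _ = trim_overlap(AdjacentPair(up, down))
        assert new_up.cigar == [("M", 50), ("S", 50)]
        assert new_up.ref_end == 1050

    def test_edge_stranded_deletion_dropped(self):
        up = make_segment(
            ref_start=1000, ref_end=1059, read_start=0, read_end=54,
            cigar=[("M", 50), ("D", 5), ("M", 4), ("S", 46)],
        )
        down = make_segment(ref_start=5000, read_start=50, read_end=100)
        new_up, _ = trim_overlap(AdjacentPair(up, down))
        assert new_up.cigar == [("M", 50), ("S", 50)]
        assert new_up.ref_end == 1050  # 4 M + 5 D removed

    def test_full_consumption_returns_none(self):
        up = make_segment(read_start=0, read_end=60)
        down = make_segment(ref_start=5000, read_start=10, read_end=55)
        new_up, new_down = trim_overlap(AdjacentPair(up, down))
        assert new_down is None
        assert new_up is not None

    @given(
        overlap=st.integers(1, 20),
        up_span=st.integers(25, 80),
        down_span=st.integers(25, 80),
        up_strand=st.sampled_from("+-"),
        down_strand=st.sampled_from("+-"),
    )
    def test_query_accounting_invariant(self, overlap, up_span, down_span, up_strand, down_strand):
        """Each side loses exactly the overlap; CIGAR query sums stay intact."""
        read_length = 200
        up = make_segment(
            ref_start=1000, strand=up_strand, read_start=0, read_end=up_span,
            read_length=read_length,
        )
        down = make_segment(
            ref_start=50_000, strand=down_strand,
            read_start=up_span - overlap, read_end=up_span - overlap + down_span,
            read_length=read_length,
        )
        new_up, new_down = trim_overlap(AdjacentPair(up, down))
        for old, new in ((up, new_up), (down, new_down)):
            if new is None:
                continue
            assert old.aligned_query_length - new.aligned_query_length == overlap
            assert cigar_query_length(new.cigar) == read_length
            assert (new.chrom, new.strand, new.mapq) == (old.chrom, old.strand, old.mapq)
        assert new_up.read_end <= new_down.read_start if new_up and new_down else True


class TestTrimChain:
    def _chain(self, spans, read_length=200):
        segs = [
            make_segment(ref_start=1000 + 10_000 * i, read_start=a, read_end=b,
                         read_length=read_length)
            for i, (a, b) in enumerate(spans)
        ]
        return MateChain("R1", segs)

    def test_no_overlap_unchanged(self):
        chain = self._chain([(0, 50), (50, 100)])
        out, stats = trim_chain(chain)
        assert [(s.read_start, s.read_end) for s in out] == [(0, 50), (50, 100)]
        assert all(not r.had_multimapping for r in stats.records)

    def test_two_junction_read_both_trimmed(self):
        chain = self._chain([(0, 54), (50, 104), (100, 150)])
        out, stats = trim_chain(chain)
        spans = [(s.read_start, s.read_end) for s in out]
        assert spans == [(0, 50), (54, 100), (104, 150)]
        assert [r.trimmed_bases for r in stats.records] == [4, 8, 4]

    def test_contained_segment_removed_and_counted(self):
        chain = self._chain([(0, 100), (20, 60), (120, 180)])
        out, stats = trim_chain(chain)
        removed = [r for r in stats.records if r.removed]
        assert len(removed) == 1
        assert removed[0].trimmed_fraction == 1.0
        for i in range(len(out.segments) - 1):
            assert out.segments[i].read_end <= out.segments[i + 1].read_start

    def test_idempotent(self):
        chain = self._chain([(0, 54), (50, 104), (100, 150)])
        once, _ = trim_chain(chain)
        twice, stats = trim_chain(once)
        assert [(s.read_start, s.read_end, s.ref_start, s.ref_end, tuple(s.cigar)) for s in once] == [
            (s.read_start, s.read_end, s.ref_start, s.ref_end, tuple(s.cigar)) for s in twice
        ]
        assert all(r.trimmed_bases == 0 for r in stats.records)

    def test_trimmed_fraction_definition(self):
        chain = self._chain([(0, 54), (50, 100)])
        _, stats = trim_chain(chain)
        assert stats.records[0].trimmed_fraction == pytest.approx(4 / 54)
        assert stats.records[1].trimmed_fraction == pytest.approx(4 / 50)

    def test_simulated_chains_pairwise_disjoint(self):
        """Brute-force overlap scan over every trimmed chain of a mixed run."""
        cfg = SimConfig(seed=9, n_read_pairs=200, fraction_sv_junctions=0.2)
        sim = simulate(cfg)
        for pair in group_pairs(iter_sam_records(sim)):
            for chain in pair.chains():
                trimmed, _ = trim_chain(chain)
                segs = trimmed.segments
                for i in range(len(segs)):
                    for j in range(i + 1, len(segs)):
                        assert (
                            segs[i].read_end <= segs[j].read_start
                            or segs[j].read_end <= segs[i].read_start
                        )
                        assert cigar_query_length(segs[i].cigar) == segs[i].read_length

    def test_sticky_end_fixture_loses_motif_length(self):
        """On duplicated-motif junctions each flank loses exactly |motif| bases."""
        cfg = SimConfig(seed=13, n_read_pairs=150, fragments_per_molecule={2: 1.0})
        sim = simulate(cfg)
        m = len(cfg.enzyme.motif)
        n_multi = 0
        for pair in group_pairs(iter_sam_records(sim)):
            for chain in pair.chains():
                _, stats = trim_chain(chain)
                for rec in stats.records:
                    if rec.had_multimapping:
                        assert rec.trimmed_bases == m
                        n_multi += 1
        assert n_multi == 2 * len(sim.molecules)  # both flanks of every junction
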