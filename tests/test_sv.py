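"""Facing-end distances, SV flagging and 1bp breakpoint calling."""

import pytest

from chromwalk.alignments import MateChain, group_pairs
from chromwalk.contacts import canonicalize
from chromwalk.digest import CutSiteIndex
from chromwalk.pipeline import PipelineConfig, process_read_pair
from chromwalk.simulate import SimConfig, iter_sam_records, simulate
from chromwalk.sv import call_breakpoints, facing_ends, facing_ends_mate_paired, flag_sv

from helpers import make_segment


@pytest.fixture()
def index():
    return CutSiteIndex({"chr1": [1000, 1050, 2080], "chr2": [500]}, {"chr1": 10_000, "chr2": 10_000})


class TestFacingEnds:
    def test_ligation_exactly_at_cut(self, index):
        up = make_segment(ref_start=1000, read_start=0, read_end=50)
        down = make_segment(chrom="chr2", ref_start=500, read_start=50, read_end=100)
        fe = facing_ends(up, down, index)
        assert (fe.end1, fe.d1) == (1050, 0)
        assert (fe.end2, fe.d2) == (500, 0)

    def test_minus_strand_downstream_faces_ref_end(self, index):
        up = make_segment(ref_start=1000, read_start=0, read_end=50)
        down = make_segment(
            ref_start=2000, ref_end=2080, strand="-", read_start=50, read_end=130,
            read_length=200,
        )
        fe = facing_ends(up, down, index)
        assert (fe.end2, fe.d2) == (2080, 0)
        assert fe.base2 == 2080

    def test_mate_paired_uses_three_prime_ends(self, index):
        s1 = make_segment(ref_start=1000, read_start=0, read_end=50)
        s2 = make_segment(chrom="chr2", ref_start=450, strand="-", read_start=0, read_end=50)
        fe = facing_ends_mate_paired(s1, s2, index)
        assert fe.end1 == 1050  # + strand 3' end = ref_end
        assert fe.end2 == 450  # - strand 3' end = ref_start
        assert fe.d2 == 50


class TestFlagSV:
    @pytest.mark.parametrize(
        "d1,d2,tol,expected",
        [(0, 0, 0, False), (0, 0, 100, False), (0, 500, 5, True), (6, 0, 5, True), (5, 5, 5, False)],
    )
    def test_or_rule(self, d1, d2, tol, expected):
        from chromwalk.sv import FacingEnds

        fe = FacingEnds(0, 1, 0, 1, d1, d2)
        assert flag_sv(fe, tol) is expected

    def test_negative_tolerance_rejected(self):
        from chromwalk.sv import FacingEnds

        with pytest.raises(ValueError):
            flag_sv(FacingEnds(0, 1, 0, 1, 0, 0), -1)


class TestCallBreakpoints:
    def test_fusion_junction_reported_at_1bp(self, index):
        # chr1 fragment ends at 5000 (distal), fused to chr2 starting 6000
        idx = CutSiteIndex({"chr1": [100], "chr2": [9000]}, {"chr1": 10_000, "chr2": 10_000})
        up = make_segment(ref_start=4950, ref_end=5000, read_start=0, read_end=50)
        down = make_segment(chrom="chr2", ref_start=6000, read_start=50, read_end=100)
        (bp,) = call_breakpoints(MateChain("R1", [up, down]), idx, tolerance=5)
        assert (bp.chrom_a, bp.pos_a) == ("chr1", 5000)
        assert (bp.chrom_b, bp.pos_b) == ("chr2", 6001)
        assert bp.dist_a > 5 and bp.dist_b > 5

    def test_proper_junction_yields_nothing(self, index):
        up = make_segment(ref_start=1000, read_start=0, read_end=50)
        down = make_segment(ref_start=1050, read_start=50, read_end=100)
        assert call_breakpoints(MateChain("R1", [up, down]), index, tolerance=5) == []

    def test_gapped_junction_excluded(self):
        idx = CutSiteIndex({"chr1": []}, {"chr1": 10_000})
        up = make_segment(ref_start=100, read_start=0, read_end=50)
        down = make_segment(ref_start=5000, read_start=60, read_end=100)
        assert call_breakpoints(MateChain("R1", [up, down]), idx, 5, max_junction_gap=0) == []
        assert len(call_breakpoints(MateChain("R1", [up, down]), idx, 5, max_junction_gap=10)) == 1

    def test_untrimmed_chain_rejected(self):
        idx = CutSiteIndex({"chr1": []}, {"chr1": 10_000})
        up = make_segment(ref_start=100, read_start=0, read_end=54)
        down = make_segment(ref_start=5000, read_start=50, read_end=100)
        with pytest.raises(ValueError, match="trimmed"):
            call_breakpoints(MateChain("R1", [up, down]), idx, 5)


@pytest.fixture(scope="module")
def run(small_sim):
    cfg = PipelineConfig(min_mapq=0, policy="all")
    results = {}
    for pair in group_pairs(iter_sam_records(small_sim)):
        results[pair.read_id] = process_read_pair(pair, small_sim.index, cfg)
    return results


def _sides(chrom_a, pos_a, chrom_b, pos_b):
    """Orientation-free junction identity (R2-read junctions come mirrored)."""
    return tuple(sorted([(chrom_a, pos_a), (chrom_b, pos_b)]))


class TestSimulatedTruth:
    """Planted-junction recovery on a mixed proper/SV simulation."""

    def test_breakpoint_recall_is_total_and_exact(self, small_sim, run):
        for mol in small_sim.molecules:
            planted = {
                _sides(j.chrom_a, j.pos_a, j.chrom_b, j.pos_b)
                for j in mol.junctions
                if j.kind == "sv"
            }
            got = {
                _sides(bp.chrom_a, bp.pos_a, bp.chrom_b, bp.pos_b)
                for bp in run[mol.read_id].breakpoints
            }
            assert got == planted

    def test_no_false_flags_on_proper_junctions(self, small_sim, run):
        """Within-mate contacts at proper junctions never carry the SV flag."""
        truth = {m.read_id: m for m in small_sim.molecules}
        for read_id, res in run.items():
            mol = truth[read_id]
            sv_pos = {j.mol_pos for j in mol.junctions if j.kind == "sv"}
            for c in res.contacts:
                if c.junction_class == "mate_paired":
                    continue
                if not c.sv_flag:
                    continue
                # every flagged within-mate contact must be a planted SV
                assert any(j.kind == "sv" for j in mol.junctions), (read_id, c)

    def test_flag_rate_matches_planted_fraction(self, small_sim, run):
        planted_sv = sum(1 for m in small_sim.molecules for j in m.junctions if j.kind == "sv")
        flagged = sum(
            1
            for res in run.values()
            for c in res.contacts
            if c.junction_class != "mate_paired" and c.sv_flag
        )
        assert flagged == planted_sv

    def test_breakpoints_subset_of_flagged_adjacent_contacts(self, small_sim, run):
        for res in run.values():
            flagged_junctions = {
                (c.junction.seg_a.chrom, c.junction.seg_b.chrom)
                for c in res.contacts
                if c.sv_flag and c.junction_class == "adjacent_softclip"
            }
            for bp in res.breakpoints:
                assert (bp.chrom_a, bp.chrom_b) in flagged_junctions

    def test_canonicalize_swaps_distances_coherently(self, small_sim, run):
        order = {c: i for i, c in enumerate(small_sim.chrom_lengths)}
        for res in run.values():
            for c in res.contacts:
                canon = canonicalize(c, order)
                if canon.flipped:
                    assert (canon.dist1, canon.dist2) == (c.dist2, c.dist1)
                else:
                    assert (canon.dist1, canon.dist2) == (c.dist1, c.dist2)

    def test_interchromosomal_breakpoints_reported(self, small_sim, run):
        trans = [
            bp
            for res in run.values()
            for bp in res.breakpoints
            if bp.chrom_a != bp.chrom_b
        ]
        cis = [
            bp
            for res in run.values()
            for bp in res.breakpoints
            if bp.chrom_a == bp.chrom_b
        ]
        assert trans and cis  # both classes present and reported
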