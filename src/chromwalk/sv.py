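"""Cut-site proximity annotation and 1bp breakpoint calling.

In a proper sticky-end ligation product, the two alignments flanking a
junction face each other exactly at restriction cut sites (up to the
overhang fill-in shift).  A contact whose facing ends are *distal* from any
cut site violates the digestion model and is more likely induced by a
structural variant.  When such a junction is read through — the two
alignments are adjacent soft-clipped parts of one read, with no unaligned
bases between them — the junction coordinates pin the SV breakpoint at
single-base resolution on both sides, intra- or interchromosomal alike.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignments import AlignmentSegment, MateChain
from .contacts import Contact, Junction
from .digest import CutSiteIndex
from .trim import find_adjacent_pairs

__all__ = [
    "FacingEnds",
    "Breakpoint",
    "facing_ends",
    "facing_ends_mate_paired",
    "flag_sv",
    "annotate_contact",
    "call_breakpoints",
]


@dataclass
class FacingEnds:
    """Junction-proximal alignment ends with their cut-site distances.

    ``end1``/``end2`` are 0-based between-base boundaries (directly
    comparable to cut positions); ``base1``/``base2`` are the 1-based
    coordinates of the junction-proximal aligned base, used for breakpoint
    reporting.
    """

    end1: int
    base1: int
    end2: int
    base2: int
    d1: int
    d2: int


@dataclass
class Breakpoint:
    chrom_a: str
    pos_a: int  # 1-based junction-proximal base
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    read_id: str
    mate: str
    dist_a: int
    dist_b: int
    source: str = "adjacent_softclip"


def _right_end(seg: AlignmentSegment) -> tuple[int, int]:
    # boundary, 1-based proximal base for the reference-right end
    return seg.ref_end, seg.ref_end


def _left_end(seg: AlignmentSegment) -> tuple[int, int]:
    return seg.ref_start, seg.ref_start + 1


def _three_prime_end(seg: AlignmentSegment) -> tuple[int, int]:
    return _right_end(seg) if seg.strand == "+" else _left_end(seg)


def _five_prime_end(seg: AlignmentSegment) -> tuple[int, int]:
    return _left_end(seg) if seg.strand == "+" else _right_end(seg)


def facing_ends(
    upstream: AlignmentSegment,
    downstream: AlignmentSegment,
    index: CutSiteIndex,
) -> FacingEnds:
    """Facing ends of a within-mate junction (segments in read order).

    The upstream segment faces the junction with its 3'-in-read terminus,
    the downstream segment with its 5'-in-read terminus.
    """
    end1, base1 = _three_prime_end(upstream)
    end2, base2 = _five_prime_end(downstream)
    return FacingEnds(
        end1=end1,
        base1=base1,
        end2=end2,
        base2=base2,
        d1=index.nearest_distance(upstream.chrom, end1),
        d2=index.nearest_distance(downstream.chrom, end2),
    )


def facing_ends_mate_paired(
    seg1: AlignmentSegment, seg2: AlignmentSegment, index: CutSiteIndex
) -> FacingEnds:
    """Facing ends of a mate-paired contact: both 3'-in-read termini.

    The junction lies in the unsequenced middle of the molecule, so each
    mate faces it with its 3' end.
    """
    end1, base1 = _three_prime_end(seg1)
    end2, base2 = _three_prime_end(seg2)
    return FacingEnds(
        end1=end1,
        base1=base1,
        end2=end2,
        base2=base2,
        d1=index.nearest_distance(seg1.chrom, end1),
        d2=index.nearest_distance(seg2.chrom, end2),
    )


def flag_sv(fe: FacingEnds, tolerance: int) -> bool:
    """True iff either facing end is further than ``tolerance`` from a cut site.

    A single distal end already violates the digestion model; both distances
    stay recorded on the contact so users can impose a stricter AND rule.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return fe.d1 > tolerance or fe.d2 > tolerance


def _junction_facing_ends(junction: Junction, index: CutSiteIndex) -> FacingEnds:
    if junction.kind == "mate_paired":
        return facing_ends_mate_paired(junction.seg_a, junction.seg_b, index)
    return facing_ends(junction.seg_a, junction.seg_b, index)


def annotate_contact(
    contact: Contact, index: CutSiteIndex, tolerance: int
) -> Contact:
    """Fill ``dist1``/``dist2``/``sv_flag`` in place from the contact's junction."""
    if contact.junction is None:
        raise ValueError("contact carries no junction information")
    fe = _junction_facing_ends(contact.junction, index)
    contact.dist1, contact.dist2 = fe.d1, fe.d2
    contact.sv_flag = flag_sv(fe, tolerance)
    return contact


def call_breakpoints(
    chain: MateChain,
    index: CutSiteIndex,
    tolerance: int,
    max_junction_gap: int = 0,
) -> list[Breakpoint]:
    """1bp breakpoints from the adjacent soft-clipped junctions of one mate.

    A junction qualifies when its flanks abut on the read (``gap_len`` at
    most ``max_junction_gap``; unread junction bases forfeit base resolution)
    and its facing ends are cut-site distal.  The chain must already be
    trimmed, otherwise the duplicated junction motif shifts the coordinates
    by up to the motif length.
    """
    out: list[Breakpoint] = []
    for pair in find_adjacent_pairs(chain):
        if pair.overlap_len > 0:
            raise ValueError("chain must be trimmed before breakpoint calling")
        if pair.gap_len > max_junction_gap:
            continue
        fe = facing_ends(pair.upstream, pair.downstream, index)
        if not flag_sv(fe, tolerance):
            continue
        out.append(
            Breakpoint(
                chrom_a=pair.upstream.chrom,
                pos_a=fe.base1,
                strand_a=pair.upstream.strand,
                chrom_b=pair.downstream.chrom,
                pos_b=fe.base2,
                strand_b=pair.downstream.strand,
                read_id=pair.upstream.read_id,
                mate=chain.mate,
                dist_a=fe.d1,
                dist_b=fe.d2,
            )
        )
    return out
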