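"""Contact calling from trimmed read-pair alignment chains.

Two policies are offered, mirroring the standard pairs-parsing vocabulary:

* **mask** — at most one two-locus contact per read pair.  A plain 1+1 pair
  yields a ``UU`` contact; a 2+1 pair is *rescued* (``RU``/``UR``) when the
  chimeric mate's 3'-in-read segment is the other mate's view of the same
  fragment end; anything more complex is masked.
* **all** — the full ligation *walk* is reconstructed (R1 chain in read
  order, then the R2 chain in reverse read order, merging the duplicated
  terminal fragment the two mates share) and every consecutive locus pair
  along the walk becomes a contact.

Reported positions follow the pairs convention: the 5'-in-read reference
coordinate of each segment, 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .alignments import AlignmentSegment, ReadPairAlignments

__all__ = [
    "Contact",
    "Junction",
    "WalkElement",
    "build_walk",
    "call_mask",
    "call_all",
    "canonicalize",
]

JunctionClass = Literal["adjacent_softclip", "gapped", "mate_paired"]


@dataclass
class Junction:
    """The read-level junction a contact was derived from.

    For within-mate junctions ``seg_a``/``seg_b`` are the upstream/downstream
    segments in read order; for mate-paired contacts they are the R1-side and
    R2-side segments and the junction base itself was never sequenced.
    """

    kind: JunctionClass
    seg_a: AlignmentSegment
    seg_b: AlignmentSegment


@dataclass
class Contact:
    read_id: str
    chrom1: str
    pos1: int  # 1-based
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    pair_type: str
    junction_class: JunctionClass
    contact_index: int = 0
    dist1: int | None = None
    dist2: int | None = None
    sv_flag: bool | None = None
    flipped: bool = False
    junction: Junction | None = None


@dataclass
class WalkElement:
    """One locus of the walk; the shared terminal fragment carries both views."""

    r1_view: AlignmentSegment | None = None
    r1_index: int = -1
    r2_view: AlignmentSegment | None = None
    r2_index: int = -1

    @property
    def primary(self) -> AlignmentSegment:
        seg = self.r1_view if self.r1_view is not None else self.r2_view
        assert seg is not None
        return seg


def _terminal_match(
    a: AlignmentSegment, b: AlignmentSegment, rescue_window: int
) -> bool:
    """Are two records the two mates' views of the same fragment end?"""
    return (
        a.chrom == b.chrom
        and a.strand != b.strand
        and abs(a.five_prime_pos - b.five_prime_pos) <= rescue_window
    )


def build_walk(pair: ReadPairAlignments, rescue_window: int) -> list[WalkElement]:
    """Reconstruct the ligation walk of ``pair``.

    R1 segments in read order, then R2 segments in reverse read order; when
    the 3'-in-read terminal segments of the two mates cover the same locus
    (same chrom, opposite strands, 5' ends within ``rescue_window``) they are
    merged into a single element.
    """
    r1 = pair.chain_r1.segments
    r2 = pair.chain_r2.segments
    walk = [WalkElement(r1_view=s, r1_index=i) for i, s in enumerate(r1)]
    tail = [
        WalkElement(r2_view=s, r2_index=i)
        for i, s in enumerate(r2)
    ][::-1]
    if walk and tail and _terminal_match(r1[-1], r2[-1], rescue_window):
        walk[-1].r2_view = r2[-1]
        walk[-1].r2_index = len(r2) - 1
        tail = tail[1:]
    return walk + tail


def _classify_junction(
    a: WalkElement, b: WalkElement, max_junction_gap: int
) -> Junction:
    if a.r1_view is not None and b.r1_view is not None and b.r1_index == a.r1_index + 1:
        up, down = a.r1_view, b.r1_view
    elif (
        a.r2_view is not None and b.r2_view is not None and a.r2_index == b.r2_index + 1
    ):
        # walk holds R2 in reverse read order: b is upstream on the R2 read
        up, down = b.r2_view, a.r2_view
    else:
        seg_a = a.r2_view if a.r1_view is None else a.r1_view
        seg_b = b.r2_view if b.r2_view is not None else b.r1_view
        return Junction("mate_paired", seg_a, seg_b)
    gap = down.read_start - up.read_end
    kind: JunctionClass = "adjacent_softclip" if gap <= max_junction_gap else "gapped"
    return Junction(kind, up, down)


def _make_contact(
    read_id: str,
    seg1: AlignmentSegment,
    seg2: AlignmentSegment,
    pair_type: str,
    junction: Junction,
    contact_index: int = 0,
) -> Contact:
    return Contact(
        read_id=read_id,
        chrom1=seg1.chrom,
        pos1=seg1.five_prime_pos,
        strand1=seg1.strand,
        chrom2=seg2.chrom,
        pos2=seg2.five_prime_pos,
        strand2=seg2.strand,
        pair_type=pair_type,
        junction_class=junction.kind,
        contact_index=contact_index,
        junction=junction,
    )


def call_mask(
    pair: ReadPairAlignments,
    rescue_window: int = 500,
    max_junction_gap: int = 0,
) -> tuple[Contact | None, str]:
    """Single two-locus contact per read pair, or none with a recorded type.

    Returns ``(contact, pair_type)``; the first character of ``pair_type``
    describes the R1 side, the second the R2 side: U unique, R rescued,
    N no alignment, M masked/complex.
    """
    r1 = pair.chain_r1.segments
    r2 = pair.chain_r2.segments
    n1, n2 = len(r1), len(r2)
    if n1 == 0 or n2 == 0:
        code = ("N" if n1 == 0 else "U", "N" if n2 == 0 else "U")
        if n1 == n2 == 0:
            code = ("N", "N")
        return None, "".join(code)
    if n1 == 1 and n2 == 1:
        junction = Junction("mate_paired", r1[0], r2[0])
        return _make_contact(pair.read_id, r1[0], r2[0], "UU", junction), "UU"
    if {n1, n2} == {2, 1}:
        if n1 == 2:
            five, three, other = r1[0], r1[1], r2[0]
            pt = "RU"
        else:
            five, three, other = r2[0], r2[1], r1[0]
            pt = "UR"
        if _terminal_match(three, other, rescue_window):
            junction = _classify_junction_segments(five, three, max_junction_gap)
            contact = _make_contact(pair.read_id, five, other, pt, junction)
            return contact, pt
    return None, "MM"


def _classify_junction_segments(
    up: AlignmentSegment, down: AlignmentSegment, max_junction_gap: int
) -> Junction:
    gap = down.read_start - up.read_end
    kind: JunctionClass = "adjacent_softclip" if gap <= max_junction_gap else "gapped"
    return Junction(kind, up, down)


def call_all(
    pair: ReadPairAlignments,
    rescue_window: int = 500,
    max_junction_gap: int = 0,
) -> list[Contact]:
    """Every adjacent locus pair along the walk; k merged loci give k-1 contacts."""
    walk = build_walk(pair, rescue_window)
    if len(walk) < 2:
        return []
    pair_type = "UU" if len(walk) == 2 else "RR"
    contacts = []
    for i in range(len(walk) - 1):
        junction = _classify_junction(walk[i], walk[i + 1], max_junction_gap)
        contacts.append(
            _make_contact(
                pair.read_id,
                walk[i].primary,
                walk[i + 1].primary,
                pair_type,
                junction,
                contact_index=i,
            )
        )
    return contacts


def canonicalize(contact: Contact, chrom_order: dict[str, int]) -> Contact:
    """Impose upper-triangle side ordering (fixed chromosome order, then pos).

    Strands, cut-site distances and the pair-type characters swap together
    with the sides; an internal ``flipped`` flag records the swap.  Idempotent.
    """
    for chrom in (contact.chrom1, contact.chrom2):
        if chrom not in chrom_order:
            raise ValueError(f"chromosome {chrom!r} not in chromosome order")
    key1 = (chrom_order[contact.chrom1], contact.pos1)
    key2 = (chrom_order[contact.chrom2], contact.pos2)
    if key1 <= key2:
        return contact
    return replace(
        contact,
        chrom1=contact.chrom2,
        pos1=contact.pos2,
        strand1=contact.strand2,
        chrom2=contact.chrom1,
        pos2=contact.pos1,
        strand2=contact.strand1,
        pair_type=contact.pair_type[::-1],
        dist1=contact.dist2,
        dist2=contact.dist1,
        flipped=not contact.flipped,
    )
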