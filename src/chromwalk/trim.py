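"""Multimapping trimming at ligation junctions.

Sticky-end proximity ligation leaves a single restriction motif at the
junction between two ligated loci, but because both flanking loci border
that motif in the reference, a local aligner maps the junction bases into
*both* adjacent soft-clipped alignments of the read.  Those bases existed
once in vivo, so the overlap is an artifact.  The trimmer removes the
read-coordinate overlap between adjacent segments of one mate from both
segments, rewriting CIGARs (removed query bases become soft clips) and
shrinking reference spans accordingly.

Trimming is generic over read-coordinate overlap, not restricted to exact
motif matches: other local-realignment artifacts produce the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignments import (
    ALIGNED_QUERY,
    AlignmentSegment,
    Cigar,
    MateChain,
    cigar_aligned_query_length,
)

__all__ = [
    "AdjacentPair",
    "SegmentTrimRecord",
    "ChainTrimStats",
    "find_adjacent_pairs",
    "trim_overlap",
    "trim_chain",
]


@dataclass
class AdjacentPair:
    """Two read-adjacent segments of one mate with their overlap/gap."""

    upstream: AlignmentSegment
    downstream: AlignmentSegment

    def __post_init__(self) -> None:
        if self.upstream.read_start > self.downstream.read_start:
            raise ValueError("upstream must not start after downstream in read")

    @property
    def overlap_len(self) -> int:
        return max(0, self.upstream.read_end - self.downstream.read_start)

    @property
    def gap_len(self) -> int:
        return max(0, self.downstream.read_start - self.upstream.read_end)


@dataclass
class SegmentTrimRecord:
    """Trimming bookkeeping for one (post-MAPQ-filter) segment."""

    read_id: str
    mate: str
    soft_clipped: bool
    original_span: int  # aligned query bases before trimming
    trimmed_bases: int = 0
    removed: bool = False

    @property
    def had_multimapping(self) -> bool:
        return self.trimmed_bases > 0

    @property
    def trimmed_fraction(self) -> float:
        return self.trimmed_bases / self.original_span if self.original_span else 0.0


@dataclass
class ChainTrimStats:
    records: list[SegmentTrimRecord] = field(default_factory=list)

    def extend(self, other: "ChainTrimStats") -> None:
        self.records.extend(other.records)


def find_adjacent_pairs(chain: MateChain) -> list[AdjacentPair]:
    """Consecutive segment pairs of a read-sorted chain."""
    segs = chain.segments
    return [AdjacentPair(segs[i], segs[i + 1]) for i in range(len(segs) - 1)]


def _strip_end(cigar: Cigar, right: bool) -> tuple[Cigar, list[tuple[str, int]]]:
    """Split off the clip ops (S/H) at one CIGAR end; returns (core, clips).

    ``clips`` is in inside-out order for the chosen end.
    """
    core = list(cigar)
    clips: list[tuple[str, int]] = []
    while core:
        op, l = core[-1] if right else core[0]
        if op in ("S", "H"):
            clips.append((op, l))
            core.pop() if right else core.pop(0)
        else:
            break
    return core, clips


def _remove_aligned_query(
    segment: AlignmentSegment, n: int, read_end: str
) -> AlignmentSegment | None:
    """Remove ``n`` aligned query bases from one read end of ``segment``.

    ``read_end`` is "5p" or "3p" *in read orientation*.  Removed query bases
    are converted to soft clip; reference-consuming ops walked over (including
    D/N stranded at the new alignment edge) shrink the reference span on the
    appropriate side.  Returns ``None`` when the whole alignment is consumed.
    """
    if n <= 0:
        return segment
    if n >= segment.aligned_query_length:
        return None
    # Which reference-orientation CIGAR side corresponds to the read end?
    right = (read_end == "3p") == (segment.strand == "+")
    core, clips = _strip_end(segment.cigar, right)
    removed_q = 0
    removed_r = 0
    while core:
        op, l = core[-1] if right else core[0]
        if removed_q < n:
            if op in ("M", "=", "X"):
                take = min(l, n - removed_q)
                removed_q += take
                removed_r += take
                if take == l:
                    core.pop() if right else core.pop(0)
                else:
                    repl = (op, l - take)
                    if right:
                        core[-1] = repl
                    else:
                        core[0] = repl
                continue
            if op == "I":
                take = min(l, n - removed_q)
                removed_q += take
                if take == l:
                    core.pop() if right else core.pop(0)
                else:
                    repl = (op, l - take)
                    if right:
                        core[-1] = repl
                    else:
                        core[0] = repl
                continue
            if op in ("D", "N"):
                removed_r += l
                core.pop() if right else core.pop(0)
                continue
            if op == "P":
                core.pop() if right else core.pop(0)
                continue
            raise ValueError(f"unexpected CIGAR op {op!r} inside alignment")
        # done removing query bases: drop D/N/P now stranded at the edge
        if op in ("D", "N"):
            removed_r += l
            core.pop() if right else core.pop(0)
        elif op == "P":
            core.pop() if right else core.pop(0)
        else:
            break
    assert removed_q == n
    # merge removed query bases into the soft clip at this end;
    # clip order at an end is S inside, H outside
    soft = removed_q + sum(l for op, l in clips if op == "S")
    hard = sum(l for op, l in clips if op == "H")
    new_end: Cigar = [("S", soft)]
    if hard:
        new_end.append(("H", hard))
    cigar = core + new_end if right else new_end[::-1] + core
    ref_start, ref_end = segment.ref_start, segment.ref_end
    if right:
        ref_end -= removed_r
    else:
        ref_start += removed_r
    if read_end == "3p":
        read_span = (segment.read_start, segment.read_end - n)
    else:
        read_span = (segment.read_start + n, segment.read_end)
    out = AlignmentSegment(
        read_id=segment.read_id,
        mate=segment.mate,
        chrom=segment.chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=segment.strand,
        mapq=segment.mapq,
        cigar=cigar,
        read_start=read_span[0],
        read_end=read_span[1],
        read_length=segment.read_length,
        is_soft_clipped=True,
        record=segment.record,
    )
    out.validate()
    return out


def trim_overlap(
    pair: AdjacentPair,
) -> tuple[AlignmentSegment | None, AlignmentSegment | None]:
    """Remove the read-coordinate overlap from *both* segments of ``pair``.

    The junction bases derive from one locus in vivo but there is no way to
    tell which, so all multimapping is removed symmetrically: the upstream
    segment loses the overlap from its 3'-in-read end, the downstream from
    its 5'-in-read end.  A segment fully consumed by the overlap comes back
    as ``None``.
    """
    n = pair.overlap_len
    if n <= 0:
        raise ValueError("trim_overlap requires overlap_len > 0")
    up = _remove_aligned_query(pair.upstream, n, "3p")
    down = _remove_aligned_query(pair.downstream, n, "5p")
    return up, down


def trim_chain(chain: MateChain) -> tuple[MateChain, ChainTrimStats]:
    """Trim every adjacent overlap in ``chain`` until read spans are disjoint.

    Returns the trimmed chain plus per-segment statistics (original aligned
    span, bases trimmed, whether the segment was removed outright).  The
    operation is idempotent and never touches chrom/strand/MAPQ.
    """
    stats = ChainTrimStats()
    recs: dict[int, SegmentTrimRecord] = {}
    segs = list(chain.segments)
    for seg in segs:
        rec = SegmentTrimRecord(
            read_id=seg.read_id,
            mate=seg.mate,
            soft_clipped=seg.is_soft_clipped,
            original_span=seg.aligned_query_length,
        )
        recs[id(seg)] = rec
        stats.records.append(rec)

    def link(old: AlignmentSegment, new: AlignmentSegment | None) -> None:
        rec = recs.pop(id(old))
        if new is None:
            rec.trimmed_bases += old.aligned_query_length
            rec.removed = True
        else:
            rec.trimmed_bases += old.aligned_query_length - new.aligned_query_length
            recs[id(new)] = rec

    while True:
        segs.sort(key=lambda s: (s.read_start, s.read_end))
        target = None
        for i in range(len(segs) - 1):
            if segs[i].read_end > segs[i + 1].read_start:
                target = i
                break
        if target is None:
            break
        up_old, down_old = segs[target], segs[target + 1]
        up, down = trim_overlap(AdjacentPair(up_old, down_old))
        link(up_old, up)
        link(down_old, down)
        repl = [s for s in (up, down) if s is not None]
        segs[target : target + 2] = repl
    out = MateChain(chain.mate, segs)
    out.sort()
    return out, stats
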