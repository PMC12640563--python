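"""Alignment model: per-mate chains of soft-clipped segments in read coordinates.

Chimeric ligation products are reported by BWA-MEM-family aligners (and the
bisulfite aligners built on them) as several soft-clipped records per mate.
Everything downstream — junction trimming, walk reconstruction, breakpoint
calling — reasons about *read* coordinates, so every record is converted to
a span on the original read as sequenced.  SAM reports clips in reference
orientation; for minus-strand records the clip lengths are flipped.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field, replace

import pysam

__all__ = [
    "AlignmentSegment",
    "MateChain",
    "ReadPairAlignments",
    "FilterStats",
    "segment_from_record",
    "group_pairs",
    "iter_pairs_from_path",
    "mapq_filter",
    "cigar_query_length",
    "cigar_reference_length",
    "cigar_aligned_query_length",
]

# CIGAR op classes (op chars as in the SAM spec)
CONSUMES_QUERY = frozenset("MIS=X")
CONSUMES_REF = frozenset("MDN=X")
ALIGNED_QUERY = frozenset("MI=X")  # query-consuming, not clipped
CLIP_OPS = frozenset("SH")

_OP_CHARS = "MIDNSHP=X"

Cigar = list[tuple[str, int]]


def cigar_query_length(cigar: Cigar, with_hard_clips: bool = True) -> int:
    ops = CONSUMES_QUERY | ({"H"} if with_hard_clips else set())
    return sum(l for op, l in cigar if op in ops)


def cigar_reference_length(cigar: Cigar) -> int:
    return sum(l for op, l in cigar if op in CONSUMES_REF)


def cigar_aligned_query_length(cigar: Cigar) -> int:
    return sum(l for op, l in cigar if op in ALIGNED_QUERY)


@dataclass
class AlignmentSegment:
    """One aligner record with reference and original-read coordinate spans.

    ``read_start``/``read_end`` are 0-based half-open on the read *as
    sequenced* (hard-clipped bases included in ``read_length``), so adjacency
    and overlap between the split parts of one chimeric read are meaningful
    regardless of which strand each part aligned to.
    """

    read_id: str
    mate: str  # "R1" | "R2"
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # "+" | "-"
    mapq: int
    cigar: Cigar
    read_start: int
    read_end: int
    read_length: int
    is_soft_clipped: bool
    record: pysam.AlignedSegment | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        if self.ref_end - self.ref_start != cigar_reference_length(self.cigar):
            raise ValueError(f"{self.read_id}: reference span disagrees with CIGAR")
        if self.read_end - self.read_start != cigar_aligned_query_length(self.cigar):
            raise ValueError(f"{self.read_id}: read span disagrees with CIGAR")
        if cigar_query_length(self.cigar) != self.read_length:
            raise ValueError(f"{self.read_id}: CIGAR query length != read length")
        if not 0 <= self.read_start < self.read_end <= self.read_length:
            raise ValueError(f"{self.read_id}: read span out of bounds")

    @property
    def aligned_query_length(self) -> int:
        return self.read_end - self.read_start

    # 5'/3'-in-read reference boundaries (0-based, between-base coordinates).
    # On the plus strand the read runs left-to-right along the reference.
    @property
    def five_prime_boundary(self) -> int:
        return self.ref_start if self.strand == "+" else self.ref_end

    @property
    def three_prime_boundary(self) -> int:
        return self.ref_end if self.strand == "+" else self.ref_start

    @property
    def five_prime_pos(self) -> int:
        """1-based reference coordinate of the read's 5'-most aligned base
        (the pairs-format reporting convention)."""
        return self.ref_start + 1 if self.strand == "+" else self.ref_end


@dataclass
class MateChain:
    mate: str
    segments: list[AlignmentSegment] = field(default_factory=list)

    def sort(self) -> None:
        self.segments.sort(key=lambda s: (s.read_start, s.read_end))

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[AlignmentSegment]:
        return iter(self.segments)


@dataclass
class ReadPairAlignments:
    read_id: str
    chain_r1: MateChain
    chain_r2: MateChain

    def chains(self) -> tuple[MateChain, MateChain]:
        return (self.chain_r1, self.chain_r2)

    def n_segments(self) -> int:
        return len(self.chain_r1) + len(self.chain_r2)


@dataclass
class FilterStats:
    """Per-run tally of MAPQ filtering."""

    segments_seen: int = 0
    segments_removed: int = 0

    def update(self, removed: int, seen: int) -> None:
        self.segments_seen += seen
        self.segments_removed += removed


def _cigar_from_record(rec: pysam.AlignedSegment) -> Cigar:
    return [(_OP_CHARS[op], l) for op, l in rec.cigartuples]


def segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    """Convert one mapped SAM record into an :class:`AlignmentSegment`.

    Raises ``ValueError`` if the CIGAR is inconsistent with the stored
    sequence length.
    """
    if rec.is_unmapped or rec.cigartuples is None:
        raise ValueError(f"{rec.query_name}: record is unmapped or lacks a CIGAR")
    cigar = _cigar_from_record(rec)
    read_length = cigar_query_length(cigar, with_hard_clips=True)
    seq = rec.query_sequence
    if seq is not None and len(seq) != cigar_query_length(cigar, with_hard_clips=False):
        raise ValueError(
            f"{rec.query_name}: CIGAR query length "
            f"{cigar_query_length(cigar, with_hard_clips=False)} != "
            f"sequence length {len(seq)}"
        )
    lead = 0
    for op, l in cigar:
        if op in CLIP_OPS:
            lead += l
        else:
            break
    trail = 0
    for op, l in reversed(cigar):
        if op in CLIP_OPS:
            trail += l
        else:
            break
    strand = "-" if rec.is_reverse else "+"
    if strand == "+":
        read_start = lead
    else:
        read_start = trail
    read_end = read_start + cigar_aligned_query_length(cigar)
    mate = "R2" if rec.is_read2 else "R1"
    seg = AlignmentSegment(
        read_id=rec.query_name,
        mate=mate,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        strand=strand,
        mapq=rec.mapping_quality,
        cigar=cigar,
        read_start=read_start,
        read_end=read_end,
        read_length=read_length,
        is_soft_clipped=any(op == "S" for op, _ in cigar),
        record=rec,
    )
    seg.validate()
    return seg


def group_pairs(records: Iterable[pysam.AlignedSegment]) -> Iterator[ReadPairAlignments]:
    """Group a name-collated record stream into one object per read name.

    Secondary (0x100) and duplicate (0x400) records are dropped; supplementary
    (0x800) records are kept as chain segments.  Unmapped mates yield empty
    chains.  Non-adjacent same-name records indicate input that is not
    name-grouped and raise ``ValueError``.
    """
    seen: set[str] = set()
    current: ReadPairAlignments | None = None
    for rec in records:
        if rec.is_secondary or rec.is_duplicate:
            continue
        name = rec.query_name
        if current is None or name != current.read_id:
            if name in seen:
                raise ValueError(
                    f"read {name!r} is not name-adjacent: input must be "
                    "name-grouped (collate/sort by name first)"
                )
            if current is not None:
                for chain in current.chains():
                    chain.sort()
                yield current
                seen.add(current.read_id)
            current = ReadPairAlignments(name, MateChain("R1"), MateChain("R2"))
        if rec.is_unmapped:
            continue
        seg = segment_from_record(rec)
        (current.chain_r1 if seg.mate == "R1" else current.chain_r2).segments.append(seg)
    if current is not None:
        for chain in current.chains():
            chain.sort()
        yield current


def iter_pairs_from_path(path: str) -> Iterator[ReadPairAlignments]:
    """Stream :class:`ReadPairAlignments` from a SAM/BAM file on disk."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        hd = fh.header.to_dict().get("HD", {})
        if hd.get("SO") == "coordinate":
            raise ValueError(
                f"{path}: header says coordinate-sorted; name-grouped input is "
                "required (run samtools collate/sort -n first)"
            )
        yield from group_pairs(fh)


def mapq_filter(
    pair: ReadPairAlignments, min_mapq: int, stats: FilterStats | None = None
) -> ReadPairAlignments:
    """Drop segments with ``mapq < min_mapq``; chains stay read-sorted."""
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    chains = []
    removed = 0
    seen = 0
    for chain in pair.chains():
        kept = [s for s in chain.segments if s.mapq >= min_mapq]
        seen += len(chain.segments)
        removed += len(chain.segments) - len(kept)
        chains.append(MateChain(chain.mate, kept))
    if stats is not None:
        stats.update(removed, seen)
    return ReadPairAlignments(pair.read_id, chains[0], chains[1])
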