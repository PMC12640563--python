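"""Output writers: trimmed BAM, annotated 4DN pairs text, BEDPE breakpoints.

All internal computation is 0-based half-open; conversion to the pairs
format's 1-based coordinates (and back to BEDPE's 0-based intervals)
happens only here, at serialization.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping

import pysam

from . import __version__
from .alignments import AlignmentSegment
from .contacts import Contact
from .sv import Breakpoint

__all__ = [
    "PAIRS_COLUMNS",
    "write_trimmed_bam",
    "write_pairs",
    "write_breakpoints",
]

PAIRS_COLUMNS = [
    "readID",
    "chrom1",
    "pos1",
    "chrom2",
    "pos2",
    "strand1",
    "strand2",
    "pair_type",
    "dist1",
    "dist2",
    "sv_flag",
    "junction_class",
    "contact_index",
]


def _cigar_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{l}{op}" for op, l in cigar if l > 0)


def write_trimmed_bam(
    segments: Iterable[AlignmentSegment],
    header: pysam.AlignmentHeader,
    path: str,
    parameters: Mapping[str, object] | None = None,
) -> int:
    """Emit surviving segments with rewritten POS/CIGAR; returns record count.

    A @PG line records the tool version and run parameters.  Mode is chosen
    from the extension (.bam binary, otherwise SAM with header).
    """
    hd = header.to_dict()
    cl = " ".join(f"{k}={v}" for k, v in (parameters or {}).items())
    hd.setdefault("PG", []).append(
        {"ID": "chromwalk", "PN": "chromwalk", "VN": __version__, "CL": cl or "-"}
    )
    new_header = pysam.AlignmentHeader.from_dict(hd)
    lengths = {sq["SN"]: sq["LN"] for sq in hd.get("SQ", [])}
    mode = "wb" if str(path).endswith(".bam") else "wh"
    n = 0
    with pysam.AlignmentFile(path, mode, header=new_header) as out:
        for seg in segments:
            if seg.ref_end > lengths.get(seg.chrom, 0):
                raise ValueError(
                    f"{seg.read_id}: ref_end {seg.ref_end} beyond {seg.chrom} length"
                )
            if seg.record is not None:
                d = seg.record.to_dict()
            else:
                d = {
                    "name": seg.read_id,
                    "flag": str(
                        0x1
                        | (0x40 if seg.mate == "R1" else 0x80)
                        | (0x10 if seg.strand == "-" else 0)
                    ),
                    "ref_name": seg.chrom,
                    "ref_pos": "0",
                    "map_quality": str(seg.mapq),
                    "cigar": "*",
                    "next_ref_name": "*",
                    "next_ref_pos": "0",
                    "length": "0",
                    "seq": "*",
                    "qual": "*",
                    "tags": [],
                }
            d["ref_pos"] = str(seg.ref_start + 1)
            d["cigar"] = _cigar_string(seg.cigar)
            out.write(pysam.AlignedSegment.from_dict(d, new_header))
            n += 1
    return n


def _fmt(value: object) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def write_pairs(
    contacts: list[Contact],
    chrom_lengths: Mapping[str, int],
    path: str,
    parameters: Mapping[str, object] | None = None,
    genome_assembly: str = "unknown",
) -> None:
    """4DN pairs v1.0 text, optionally bgzip-compressed (``.gz`` suffix).

    Contacts must already be canonical (upper-triangle side ordering by the
    ``chrom_lengths`` order); rows are sorted by (chrom1, chrom2, pos1, pos2).
    """
    order = {chrom: i for i, chrom in enumerate(chrom_lengths)}
    for c in contacts:
        k1 = (order[c.chrom1], c.pos1)
        k2 = (order[c.chrom2], c.pos2)
        if k1 > k2:
            raise ValueError(f"non-canonical contact for read {c.read_id}")
    rows = sorted(
        contacts, key=lambda c: (order[c.chrom1], order[c.chrom2], c.pos1, c.pos2)
    )
    lines = ["## pairs format v1.0"]
    lines.append("#sorted: chr1-chr2-pos1-pos2")
    lines.append("#shape: upper triangle")
    lines.append(f"#genome_assembly: {genome_assembly}")
    for chrom, length in chrom_lengths.items():
        lines.append(f"#chromsize: {chrom} {length}")
    if parameters:
        cl = " ".join(f"{k}={v}" for k, v in parameters.items())
        lines.append(f"#command: chromwalk {cl}")
    lines.append("#columns: " + " ".join(PAIRS_COLUMNS))
    for c in rows:
        lines.append(
            "\t".join(
                [
                    c.read_id,
                    c.chrom1,
                    str(c.pos1),
                    c.chrom2,
                    str(c.pos2),
                    c.strand1,
                    c.strand2,
                    c.pair_type,
                    _fmt(c.dist1),
                    _fmt(c.dist2),
                    _fmt(c.sv_flag),
                    c.junction_class,
                    str(c.contact_index),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if str(path).endswith(".gz"):
        with pysam.BGZFile(str(path), "w") as fh:
            fh.write(text.encode())
    else:
        with open(path, "w") as fh:
            fh.write(text)


def write_breakpoints(
    breakpoints: list[Breakpoint],
    chrom_lengths: Mapping[str, int],
    path: str,
    per_read_path: str | None = None,
) -> None:
    """BEDPE breakpoints, one aggregate row per unique junction.

    Intervals are 0-based half-open single bases; the score column carries
    the supporting-read count for the junction, the name column the first
    supporting read.  An optional second file lists every supporting read.
    """
    order = {chrom: i for i, chrom in enumerate(chrom_lengths)}

    def canonical(bp: Breakpoint) -> tuple:
        a = (order[bp.chrom_a], bp.pos_a, bp.strand_a)
        b = (order[bp.chrom_b], bp.pos_b, bp.strand_b)
        if a <= b:
            return (bp.chrom_a, bp.pos_a, bp.strand_a, bp.chrom_b, bp.pos_b, bp.strand_b)
        return (bp.chrom_b, bp.pos_b, bp.strand_b, bp.chrom_a, bp.pos_a, bp.strand_a)

    support: Counter[tuple] = Counter()
    first_read: dict[tuple, str] = {}
    for bp in breakpoints:
        key = canonical(bp)
        support[key] += 1
        first_read.setdefault(key, bp.read_id)

    def sort_key(key: tuple) -> tuple:
        return (order[key[0]], key[1], order[key[3]], key[4])

    with open(path, "w") as fh:
        for key in sorted(support, key=sort_key):
            ca, pa, sa, cb, pb, sb = key
            fh.write(
                f"{ca}\t{pa - 1}\t{pa}\t{cb}\t{pb - 1}\t{pb}\t"
                f"{first_read[key]}\t{support[key]}\t{sa}\t{sb}\n"
            )
    if per_read_path is not None:
        with open(per_read_path, "w") as fh:
            for bp in breakpoints:
                ca, pa, sa, cb, pb, sb = canonical(bp)
                fh.write(
                    f"{ca}\t{pa - 1}\t{pa}\t{cb}\t{pb - 1}\t{pb}\t"
                    f"{bp.read_id}\t1\t{sa}\t{sb}\n"
                )
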