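"""End-to-end orchestration: name-grouped alignments in, contacts/BAM/QC out.

Processing is streaming with constant memory per read: the only whole-genome
state held is the cut-site index, the (small) contact and breakpoint lists
collected for sorted output, and the QC counters.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import pysam

from .alignments import (
    AlignmentSegment,
    FilterStats,
    ReadPairAlignments,
    group_pairs,
    mapq_filter,
)
from .contacts import Contact, call_all, call_mask, canonicalize
from .digest import CutSiteIndex
from .qc import QCReport, compute_qc
from .sv import Breakpoint, annotate_contact, call_breakpoints
from .trim import SegmentTrimRecord, trim_chain
from .writers import write_breakpoints, write_pairs, write_trimmed_bam

__all__ = ["PipelineConfig", "ReadResult", "PipelineResult", "process_read_pair", "run"]


@dataclass
class PipelineConfig:
    min_mapq: int = 30
    policy: str = "mask"  # "mask" | "all"
    sv_tolerance: int | None = None  # None -> |motif| + 1 from the index
    max_junction_gap: int = 0
    rescue_window: int = 500

    def resolve_tolerance(self, index: CutSiteIndex) -> int:
        if self.sv_tolerance is not None:
            return self.sv_tolerance
        tol = index.default_sv_tolerance
        if tol is None:
            raise ValueError(
                "sv_tolerance must be given when the cut-site index has no "
                "enzyme provenance (e.g. loaded from BED)"
            )
        return tol

    def to_dict(self) -> dict:
        return {
            "min_mapq": self.min_mapq,
            "policy": self.policy,
            "sv_tolerance": self.sv_tolerance,
            "max_junction_gap": self.max_junction_gap,
            "rescue_window": self.rescue_window,
        }


@dataclass
class ReadResult:
    read_id: str
    pair_type: str
    contacts: list[Contact]
    breakpoints: list[Breakpoint]
    segments: list[AlignmentSegment]
    trim_records: list[SegmentTrimRecord]


def process_read_pair(
    pair: ReadPairAlignments,
    index: CutSiteIndex,
    config: PipelineConfig,
    filter_stats: FilterStats | None = None,
) -> ReadResult:
    """Filter, trim, call contacts and breakpoints for one read pair."""
    tolerance = config.resolve_tolerance(index)
    pair = mapq_filter(pair, config.min_mapq, filter_stats)
    trim_records: list[SegmentTrimRecord] = []
    chains = []
    for chain in pair.chains():
        trimmed, stats = trim_chain(chain)
        trim_records.extend(stats.records)
        chains.append(trimmed)
    pair = ReadPairAlignments(pair.read_id, chains[0], chains[1])

    if config.policy == "mask":
        contact, pair_type = call_mask(
            pair, config.rescue_window, config.max_junction_gap
        )
        contacts = [contact] if contact is not None else []
    elif config.policy == "all":
        contacts = call_all(pair, config.rescue_window, config.max_junction_gap)
        if contacts:
            pair_type = contacts[0].pair_type
        else:
            pair_type = ("U" if len(pair.chain_r1) else "N") + (
                "U" if len(pair.chain_r2) else "N"
            )
    else:
        raise ValueError(f"unknown contact policy {config.policy!r}")

    for contact in contacts:
        annotate_contact(contact, index, tolerance)

    breakpoints: list[Breakpoint] = []
    for chain in pair.chains():
        breakpoints.extend(
            call_breakpoints(chain, index, tolerance, config.max_junction_gap)
        )

    segments = list(pair.chain_r1.segments) + list(pair.chain_r2.segments)
    return ReadResult(
        pair.read_id, pair_type, contacts, breakpoints, segments, trim_records
    )


@dataclass
class PipelineResult:
    qc: QCReport
    contacts: list[Contact] = field(default_factory=list)  # canonicalized
    breakpoints: list[Breakpoint] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    results: list[ReadResult] = field(default_factory=list)


def _header_chrom_lengths(header: pysam.AlignmentHeader) -> dict[str, int]:
    return {sq["SN"]: sq["LN"] for sq in header.to_dict().get("SQ", [])}


def run(
    alignments: str | Iterable[pysam.AlignedSegment],
    index: CutSiteIndex,
    config: PipelineConfig | None = None,
    out_prefix: str | None = None,
    header: pysam.AlignmentHeader | None = None,
    keep_results: bool = False,
) -> PipelineResult:
    """Run the full pipeline over a name-grouped SAM/BAM path or record stream.

    With ``out_prefix`` the four standard outputs are written:
    ``<prefix>.trimmed.bam``, ``<prefix>.pairs``, ``<prefix>.breakpoints.bedpe``
    and ``<prefix>.qc.json`` / ``.qc.tsv``.
    """
    config = config or PipelineConfig()
    close_me = None
    if isinstance(alignments, str):
        fh = pysam.AlignmentFile(alignments, check_sq=False)
        hd = fh.header.to_dict().get("HD", {})
        if hd.get("SO") == "coordinate":
            fh.close()
            raise ValueError(
                f"{alignments}: coordinate-sorted input; name-grouped input is "
                "required (samtools collate/sort -n first)"
            )
        header = fh.header
        records: Iterator[pysam.AlignedSegment] = iter(fh)
        close_me = fh
    else:
        if header is None:
            raise ValueError("header is required for in-memory record streams")
        records = iter(alignments)

    chrom_lengths = _header_chrom_lengths(header)
    unknown = set(chrom_lengths) - set(index.chrom_lengths)
    if unknown:
        raise ValueError(
            f"alignment header chromosomes missing from cut-site index: "
            f"{sorted(unknown)}"
        )
    chrom_order = {chrom: i for i, chrom in enumerate(chrom_lengths)}

    filter_stats = FilterStats()
    contacts: list[Contact] = []
    breakpoints: list[Breakpoint] = []
    trim_records: list[SegmentTrimRecord] = []
    pair_types: list[str] = []
    results: list[ReadResult] = []
    n_pairs = 0

    params = config.to_dict()
    params["sv_tolerance"] = config.resolve_tolerance(index)
    all_segments: list[AlignmentSegment] = []
    try:
        for pair in group_pairs(records):
            n_pairs += 1
            res = process_read_pair(pair, index, config, filter_stats)
            pair_types.append(res.pair_type)
            for contact in res.contacts:
                contacts.append(canonicalize(contact, chrom_order))
            breakpoints.extend(res.breakpoints)
            trim_records.extend(res.trim_records)
            if out_prefix is not None:
                all_segments.extend(res.segments)
            if keep_results:
                results.append(res)
    finally:
        if close_me is not None:
            close_me.close()

    qc = compute_qc(
        contacts, trim_records, filter_stats, breakpoints, pair_types, n_pairs,
        parameters=params,
    )
    result = PipelineResult(qc, contacts, breakpoints, chrom_lengths, results)

    if out_prefix is not None:
        write_trimmed_bam(all_segments, header, f"{out_prefix}.trimmed.bam", params)
        write_pairs(contacts, chrom_lengths, f"{out_prefix}.pairs", params)
        write_breakpoints(breakpoints, chrom_lengths, f"{out_prefix}.breakpoints.bedpe")
        qc.to_json(f"{out_prefix}.qc.json")
        qc.to_tsv(f"{out_prefix}.qc.tsv")
    return result
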