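"""Per-cell quality-control metrics.

The headline data-quality indicator for chromatin-conformation data is the
intrachromosomal-to-interchromosomal (cis/trans) contact ratio; low ratios
flag libraries dominated by random inter-molecular ligation or spurious
alignments.  Trimming statistics summarise how much junction multimapping
the library carried.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

from .alignments import FilterStats
from .contacts import Contact
from .sv import Breakpoint
from .trim import SegmentTrimRecord

__all__ = ["QCReport", "compute_qc", "merge_reports"]


@dataclass
class QCReport:
    total_read_pairs: int = 0
    segments_total: int = 0
    segments_filtered_by_mapq: int = 0
    segments_removed_by_trimming: int = 0
    softclipped_segments: int = 0
    softclipped_with_multimapping: int = 0
    trimmed_fraction_mean: float | None = None
    trimmed_fraction_std: float | None = None
    contacts_total: int = 0
    contacts_cis: int = 0
    contacts_trans: int = 0
    cis_trans_ratio: float | None = None
    pair_type_counts: dict[str, int] = field(default_factory=dict)
    sv_flagged_contacts: int = 0
    breakpoints_total: int = 0
    unique_breakpoints: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_read_pairs": self.total_read_pairs,
            "segments_total": self.segments_total,
            "segments_filtered_by_mapq": self.segments_filtered_by_mapq,
            "segments_removed_by_trimming": self.segments_removed_by_trimming,
            "softclipped_segments": self.softclipped_segments,
            "softclipped_with_multimapping": self.softclipped_with_multimapping,
            "trimmed_fraction_mean": self.trimmed_fraction_mean,
            "trimmed_fraction_std": self.trimmed_fraction_std,
            "contacts_total": self.contacts_total,
            "contacts_cis": self.contacts_cis,
            "contacts_trans": self.contacts_trans,
            "cis_trans_ratio": self.cis_trans_ratio,
            "pair_type_counts": dict(sorted(self.pair_type_counts.items())),
            "sv_flagged_contacts": self.sv_flagged_contacts,
            "breakpoints_total": self.breakpoints_total,
            "unique_breakpoints": self.unique_breakpoints,
            "parameters": self.parameters,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        """Flat key/value TSV for eyeballing; nested fields are summarised."""
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, value in d.items():
                if key == "pair_type_counts":
                    for pt, n in value.items():
                        fh.write(f"pair_type.{pt}\t{n}\n")
                elif key == "unique_breakpoints":
                    fh.write(f"unique_breakpoints\t{len(value)}\n")
                elif key == "parameters":
                    continue
                else:
                    fh.write(f"{key}\t{value}\n")


def _mean_std(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / len(values)
    return mean, math.sqrt(var)


def compute_qc(
    contacts: list[Contact],
    trim_records: list[SegmentTrimRecord],
    filter_stats: FilterStats,
    breakpoints: list[Breakpoint],
    pair_types: list[str],
    total_read_pairs: int,
    parameters: dict | None = None,
) -> QCReport:
    """Aggregate one cell/run into a :class:`QCReport`.

    ``pair_types`` holds one code per read pair (including the uncallable
    N/M codes that never produced a contact).  Deterministic given inputs.
    """
    report = QCReport(parameters=parameters or {})
    report.total_read_pairs = total_read_pairs
    report.segments_total = filter_stats.segments_seen
    report.segments_filtered_by_mapq = filter_stats.segments_removed

    soft = [r for r in trim_records if r.soft_clipped]
    multi = [r for r in soft if r.had_multimapping]
    report.softclipped_segments = len(soft)
    report.softclipped_with_multimapping = len(multi)
    report.segments_removed_by_trimming = sum(1 for r in trim_records if r.removed)
    mean, std = _mean_std([r.trimmed_fraction for r in multi])
    report.trimmed_fraction_mean = mean
    report.trimmed_fraction_std = std

    report.contacts_total = len(contacts)
    report.contacts_cis = sum(1 for c in contacts if c.chrom1 == c.chrom2)
    report.contacts_trans = report.contacts_total - report.contacts_cis
    if report.contacts_trans > 0:
        report.cis_trans_ratio = report.contacts_cis / report.contacts_trans
    else:
        report.cis_trans_ratio = None

    report.pair_type_counts = dict(Counter(pair_types))
    report.sv_flagged_contacts = sum(1 for c in contacts if c.sv_flag)
    report.breakpoints_total = len(breakpoints)

    support: Counter[tuple] = Counter()
    for bp in breakpoints:
        key = (bp.chrom_a, bp.pos_a, bp.strand_a, bp.chrom_b, bp.pos_b, bp.strand_b)
        support[key] += 1
    report.unique_breakpoints = [
        {
            "chrom_a": k[0],
            "pos_a": k[1],
            "strand_a": k[2],
            "chrom_b": k[3],
            "pos_b": k[4],
            "strand_b": k[5],
            "support": n,
        }
        for k, n in sorted(support.items())
    ]
    return report


def merge_reports(reports: list[dict]) -> "pandas.DataFrame":  # noqa: F821
    """Cross-cell tabulation of scalar QC fields with mean/std summary rows."""
    import pandas as pd

    scalar_keys = [
        "total_read_pairs",
        "segments_total",
        "segments_filtered_by_mapq",
        "segments_removed_by_trimming",
        "softclipped_segments",
        "softclipped_with_multimapping",
        "trimmed_fraction_mean",
        "trimmed_fraction_std",
        "contacts_total",
        "contacts_cis",
        "contacts_trans",
        "cis_trans_ratio",
        "sv_flagged_contacts",
        "breakpoints_total",
    ]
    rows = []
    for i, rep in enumerate(reports):
        row = {"cell": rep.get("parameters", {}).get("label", f"cell{i}")}
        for key in scalar_keys:
            row[key] = rep.get(key)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("cell")
    summary = df.agg(["mean", "std"])
    out = pd.concat([df, summary])
    out.index.name = "cell"
    return out
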