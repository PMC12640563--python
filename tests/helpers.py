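"""Independent oracles and small builders shared by the test suite.

Everything here is deliberately naive (character scans, op-by-op walks,
line-by-line format checks) and never calls the code paths it is used to
verify.
"""

from __future__ import annotations

import pysam

from chromwalk.alignments import AlignmentSegment
from chromwalk.digest import reverse_complement

# ---------------------------------------------------------------------------
# digestion oracle


def naive_cut_sites(seq: str, motif: str, cut_offset: int) -> set[int]:
    """Character-by-character scan on both strands."""
    seq = seq.upper()
    motif = motif.upper()
    m = len(motif)
    rc = reverse_complement(motif)
    sites: set[int] = set()
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if window == motif:
            sites.add(i + cut_offset)
        if motif != rc and window == rc:
            sites.add(i + m - cut_offset)
    return sites


def naive_nearest(sites: list[int], pos: int) -> int:
    return min((abs(pos - c) for c in sites), default=2**31)


# ---------------------------------------------------------------------------
# CIGAR oracle


def cigar_walk(cigar: list[tuple[str, int]], strand: str) -> dict:
    """Op-by-op accounting of query/reference consumption and clip layout."""
    ref = 0
    aligned_query = 0
    total_query = 0
    lead_clip = 0
    trail_clip = 0
    seen_core = False
    for op, length in cigar:
        if op in "SH":
            if seen_core:
                trail_clip += length
            else:
                lead_clip += length
            total_query += length
            continue
        seen_core = True
        if op in "MIS=X":
            aligned_query += length if op != "S" else 0
            total_query += length
        if op in "MDN=X":
            ref += length
    if strand == "+":
        read_start = lead_clip
    else:
        read_start = trail_clip
    return {
        "read_start": read_start,
        "read_end": read_start + aligned_query,
        "read_length": total_query,
        "ref_length": ref,
        "aligned_query": aligned_query,
    }


def random_cigar(rng) -> list[tuple[str, int]]:
    """A structurally valid soft/hard-clipped CIGAR with indels."""
    cigar: list[tuple[str, int]] = []
    if rng.random() < 0.3:
        cigar.append(("H", int(rng.integers(1, 20))))
    if rng.random() < 0.7:
        cigar.append(("S", int(rng.integers(1, 40))))
    n_core = int(rng.integers(1, 5))
    for i in range(n_core):
        cigar.append(("M", int(rng.integers(1, 60))))
        if i < n_core - 1:
            op = "I" if rng.random() < 0.5 else "D"
            cigar.append((op, int(rng.integers(1, 10))))
    if rng.random() < 0.7:
        cigar.append(("S", int(rng.integers(1, 40))))
    if rng.random() < 0.3:
        cigar.append(("H", int(rng.integers(1, 20))))
    return cigar


# ---------------------------------------------------------------------------
# record / segment builders


def make_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
            "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
        }
    )


def make_record(
    header: pysam.AlignmentHeader,
    name: str = "read1",
    chrom: str = "chr1",
    pos: int = 100,
    strand: str = "+",
    cigar: list[tuple[str, int]] | str = "50M",
    mate: str = "R1",
    mapq: int = 60,
    flags_extra: int = 0,
) -> pysam.AlignedSegment:
    ops = "MIDNSHP=X"
    if isinstance(cigar, str):
        parsed = []
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                parsed.append((ch, int(num)))
                num = ""
        cigar = parsed
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = list(header.references).index(chrom)
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigartuples = [(ops.index(op), l) for op, l in cigar]
    seq_len = sum(l for op, l in cigar if op in "MIS=X")
    rec.query_sequence = "A" * seq_len
    rec.query_qualities = pysam.qualitystring_to_array("I" * seq_len)
    flag = 0x1 | (0x40 if mate == "R1" else 0x80) | flags_extra
    if strand == "-":
        flag |= 0x10
    rec.flag = flag
    return rec


def make_segment(
    read_id: str = "r",
    mate: str = "R1",
    chrom: str = "chr1",
    ref_start: int = 0,
    ref_end: int | None = None,
    strand: str = "+",
    read_start: int = 0,
    read_end: int = 50,
    read_length: int = 100,
    mapq: int = 60,
    cigar: list[tuple[str, int]] | None = None,
) -> AlignmentSegment:
    """Match-only segment with clips derived from the read span."""
    span = read_end - read_start
    if ref_end is None:
        ref_end = ref_start + span
    if cigar is None:
        lead, trail = read_start, read_length - read_end
        if strand == "-":
            lead, trail = trail, lead
        cigar = [(op, l) for op, l in (("S", lead), ("M", span), ("S", trail)) if l > 0]
    seg = AlignmentSegment(
        read_id=read_id,
        mate=mate,
        chrom=chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        mapq=mapq,
        cigar=cigar,
        read_start=read_start,
        read_end=read_end,
        read_length=read_length,
        is_soft_clipped=any(op == "S" for op, _ in cigar),
    )
    seg.validate()
    return seg


# ---------------------------------------------------------------------------
# pairs-format validator (independent of chromwalk.writers)


def validate_pairs_text(text: str) -> dict:
    """Check 4DN pairs text line by line; returns parsed rows and chromsizes.

    Raises AssertionError on any format violation: missing magic line,
    undeclared columns, out-of-bounds or non-1-based coordinates, lower
    triangle rows, or unsorted body.
    """
    lines = text.splitlines()
    assert lines, "empty pairs file"
    assert lines[0] == "## pairs format v1.0", "missing pairs magic line"
    chromsizes: dict[str, int] = {}
    columns: list[str] | None = None
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("#"):
            assert body_start is None, "header line after body"
            if line.startswith("#chromsize:"):
                _, chrom, size = line.split()
                assert chrom not in chromsizes, f"duplicate chromsize {chrom}"
                chromsizes[chrom] = int(size)
            elif line.startswith("#columns:"):
                columns = line.split()[1:]
        else:
            if body_start is None:
                body_start = i
    assert columns is not None, "missing #columns line"
    assert chromsizes, "missing #chromsize lines"
    for core in ("readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"):
        assert core in columns, f"missing core column {core}"
    order = {c: i for i, c in enumerate(chromsizes)}
    col = {c: i for i, c in enumerate(columns)}
    rows = []
    prev_key = None
    for line in lines[body_start:] if body_start is not None else []:
        fields = line.split("\t")
        assert len(fields) == len(columns), f"column count mismatch: {line!r}"
        c1, c2 = fields[col["chrom1"]], fields[col["chrom2"]]
        p1, p2 = int(fields[col["pos1"]]), int(fields[col["pos2"]])
        s1, s2 = fields[col["strand1"]], fields[col["strand2"]]
        assert c1 in chromsizes and c2 in chromsizes, f"unknown chrom in {line!r}"
        assert 1 <= p1 <= chromsizes[c1], f"pos1 out of bounds: {line!r}"
        assert 1 <= p2 <= chromsizes[c2], f"pos2 out of bounds: {line!r}"
        assert s1 in "+-" and s2 in "+-", f"bad strand: {line!r}"
        assert (order[c1], p1) <= (order[c2], p2), f"lower-triangle row: {line!r}"
        key = (order[c1], order[c2], p1, p2)
        if prev_key is not None:
            assert key >= prev_key, f"unsorted row: {line!r}"
        prev_key = key
        rows.append(dict(zip(columns, fields)))
    return {"chromsizes": chromsizes, "columns": columns, "rows": rows}


# ---------------------------------------------------------------------------
# truth-based contact enumerators (operate on the simulator's truth table)


def _five_prime_pos(strand: str, ref_start: int, ref_end: int) -> int:
    return ref_start + 1 if strand == "+" else ref_end


def truth_record_tuple(rec) -> tuple:
    """(chrom, pos, strand) the pipeline should report for a truth record."""
    return (
        rec.chrom,
        _five_prime_pos(rec.strand, rec.trimmed_ref_start, rec.trimmed_ref_end),
        rec.strand,
    )


def expected_all_contacts(mol, chrom_order: dict[str, int]) -> list[tuple]:
    """Expected canonical contact side-tuples under the all policy.

    One contact per consecutive fragment pair, each side reported from its
    R1 record when one exists, else its R2 record (post-trim coordinates).
    """
    reps = {}
    for rec in mol.records:
        if rec.frag_index not in reps or rec.mate == "R1":
            if rec.frag_index in reps and reps[rec.frag_index].mate == "R1":
                continue
            reps[rec.frag_index] = rec
    out = []
    for i in range(len(mol.fragments) - 1):
        a = truth_record_tuple(reps[i])
        b = truth_record_tuple(reps[i + 1])
        if (chrom_order[a[0]], a[1]) > (chrom_order[b[0]], b[1]):
            a, b = b, a
        out.append((a[0], a[1], a[2], b[0], b[1], b[2]))
    return out


def expected_mask_outcome(mol, chrom_order: dict[str, int]):
    """Brute-force expected mask result from the truth table.

    Returns (contact-tuple or None, pair_type) following the policy:
    one segment per mate -> UU between them; a 2+1 read whose chimeric 3'
    segment is the other mate's view of the same fragment -> rescue between
    the two 5' segments; anything else masked.
    """
    r1 = sorted((r for r in mol.records if r.mate == "R1"), key=lambda r: r.trimmed_read_start)
    r2 = sorted((r for r in mol.records if r.mate == "R2"), key=lambda r: r.trimmed_read_start)

    def contact(a, b):
        ta, tb = truth_record_tuple(a), truth_record_tuple(b)
        if (chrom_order[ta[0]], ta[1]) > (chrom_order[tb[0]], tb[1]):
            ta, tb = tb, ta
        return (ta[0], ta[1], ta[2], tb[0], tb[1], tb[2])

    if len(r1) == 1 and len(r2) == 1:
        return contact(r1[0], r2[0]), "UU"
    if len(r1) == 2 and len(r2) == 1 and r1[1].frag_index == r2[0].frag_index:
        return contact(r1[0], r2[0]), "RU"
    if len(r2) == 2 and len(r1) == 1 and r2[1].frag_index == r1[0].frag_index:
        return contact(r2[0], r1[0]), "UR"
    return None, "MM"
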