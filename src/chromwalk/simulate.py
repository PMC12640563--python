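"""Synthetic ligation-product simulator with ground truth.

Generates a random reference genome, in-silico proximity-ligation molecules
(walks of 1-5 restriction fragments), and the soft-clipped SAM records a
BWA-MEM-style local aligner would report for them — bypassing alignment
itself, since the processing contract starts at aligned records.

Two junction types are planted:

* **proper** junctions join fragments at restriction-motif boundaries.  With
  ``duplicate_motif_at_junction`` the single junction motif is emitted inside
  *both* flanking alignments (the upstream alignment extends ``|motif|``
  bases through the junction into the reference motif bordering its locus),
  reproducing the sticky-end multimapping artifact with a known overlap.
* **sv** junctions join fragments at random coordinates at least a
  configured distance from any cut site, emulating reads that run through a
  structural-variant breakpoint; the exact 1bp junction coordinates are
  recorded as truth.

Molecules are laid out so that the two mate reads tile the molecule with a
small overlap inside a single shared fragment and every junction falls
cleanly inside exactly one mate's window — the configuration in which the
full walk is recoverable.  The truth table stores, per emitted record, both
the nominal span and the span expected after multimapping trimming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .digest import CutSiteIndex, EnzymeSpec, digest, find_motif_starts, reverse_complement

__all__ = [
    "SimConfig",
    "FragmentTruth",
    "JunctionTruth",
    "RecordTruth",
    "MoleculeTruth",
    "Simulation",
    "simulate",
    "simulate_genome",
    "emit_sam",
    "write_truth_tsv",
]

_MARGIN = 25  # min junction distance from window edges, bp


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 300_000
    enzyme: EnzymeSpec = field(default_factory=lambda: EnzymeSpec("DpnII", "GATC", 0))
    n_read_pairs: int = 1000
    read_length: int = 150
    # walk-size distribution: {fragments_per_molecule: probability}
    fragments_per_molecule: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.45, 3: 0.25, 4: 0.10, 5: 0.05}
    )
    fraction_sv_junctions: float = 0.0
    sv_distal_distance: tuple[int, int] = (50, 2000)
    fraction_trans: float = 0.2
    duplicate_motif_at_junction: bool = True
    low_mapq_fraction: float = 0.0
    low_mapq_value: int = 3

    def __post_init__(self) -> None:
        m = len(self.enzyme.motif)
        for name in ("fraction_sv_junctions", "fraction_trans", "low_mapq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.read_length < 2 * m + 20:
            raise ValueError("read_length must be >= 2*|motif| + 20")
        total = sum(self.fragments_per_molecule.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("fragments_per_molecule probabilities must sum to 1")
        if any(k < 1 or k > 5 for k in self.fragments_per_molecule):
            raise ValueError("fragments_per_molecule supports walks of 1-5 fragments")
        if self.read_length < 110:
            raise ValueError("read_length must be >= 110 for the molecule layout")
        if self.duplicate_motif_at_junction and not self.enzyme.is_palindromic:
            raise ValueError(
                "motif duplication modelling requires a palindromic motif"
            )
        if self.chromosome_length < 10_000:
            raise ValueError("chromosome_length must be >= 10 kb")

    @classmethod
    def from_toml(cls, path: str) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "enzyme" in raw:
            e = raw["enzyme"]
            raw["enzyme"] = EnzymeSpec(e.get("name", "custom"), e["motif"], e["cut_offset"])
        if "fragments_per_molecule" in raw:
            raw["fragments_per_molecule"] = {
                int(k): float(v) for k, v in raw["fragments_per_molecule"].items()
            }
        if "sv_distal_distance" in raw:
            raw["sv_distal_distance"] = tuple(raw["sv_distal_distance"])
        return cls(**raw)


@dataclass
class FragmentTruth:
    index: int
    chrom: str
    start: int  # 0-based half-open reference interval
    end: int
    strand: str  # orientation within the molecule
    mol_start: int
    mol_end: int


@dataclass
class JunctionTruth:
    index: int
    kind: str  # "proper" | "sv"
    mol_pos: int
    chrom_a: str
    pos_a: int  # 1-based junction-proximal base, upstream side
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    overlap: int  # planted read-coordinate multimapping, bp
    visible_mate: str  # "R1" | "R2"
    dist_a: int  # nearest-cut-site distances of the junction boundaries
    dist_b: int


@dataclass
class RecordTruth:
    mate: str
    frag_index: int
    chrom: str
    strand: str  # strand of the SAM record
    ref_start: int
    ref_end: int
    read_start: int  # original-read orientation, 0-based half-open
    read_end: int
    trimmed_ref_start: int  # expected span after multimapping trimming
    trimmed_ref_end: int
    trimmed_read_start: int
    trimmed_read_end: int
    is_primary: bool
    mapq: int


@dataclass
class MoleculeTruth:
    read_id: str
    fragments: list[FragmentTruth]
    junctions: list[JunctionTruth]
    records: list[RecordTruth]
    molecule_length: int
    r1_seq: str = ""
    r2_seq: str = ""


@dataclass
class Simulation:
    config: SimConfig
    genome: dict[str, str]
    index: CutSiteIndex
    motif_starts: dict[str, np.ndarray]
    molecules: list[MoleculeTruth]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], CutSiteIndex, dict[str, np.ndarray]]:
    """Uniform-random genome plus its naive-scan cut-site truth."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        draws = rng.integers(0, 4, size=config.chromosome_length)
        genome[f"chr{i + 1}"] = alphabet[draws].tobytes().decode()
    index = digest(genome, config.enzyme)
    starts = {
        chrom: np.asarray(find_motif_starts(seq, config.enzyme.motif), dtype=np.int64)
        for chrom, seq in genome.items()
    }
    return genome, index, starts


class _FragmentSampler:
    """Places one fragment on the reference subject to its end constraints."""

    def __init__(self, sim_genome, index, motif_starts, config, rng):
        self.index = index
        self.starts = motif_starts
        self.cfg = config
        self.rng = rng
        self.m = len(config.enzyme.motif)
        self.lengths = {c: len(s) for c, s in sim_genome.items()}

    def _boundary_pool(self, chrom: str, strand: str) -> np.ndarray:
        # proper boundaries sit at motif starts (+ strand) or motif starts
        # shifted by |motif| (- strand), so each fragment's molecule-oriented
        # sequence begins with the motif and borders one in the reference
        shift = self.m if strand == "-" else 0
        return self.starts[chrom] + shift

    def _distal(self, chrom: str, pos: int) -> bool:
        return self.index.nearest_distance(chrom, pos) >= self.cfg.sv_distal_distance[0]

    def sample(
        self,
        chrom: str,
        strand: str,
        length_window: tuple[int, int],
        type5: str,
        type3: str,
    ) -> tuple[int, int] | None:
        """Reference interval [a, b) with molecule-5'/3' ends of the given
        types ("proper", "sv" or "free"); None if placement failed."""
        lo, hi = int(length_window[0]), int(length_window[1])
        lo = max(lo, 20)
        if hi < lo:
            return None
        left_type = type5 if strand == "+" else type3
        right_type = type3 if strand == "+" else type5
        pool = self._boundary_pool(chrom, strand)
        L = self.lengths[chrom]
        bound_lo = 2 * self.m + 2
        bound_hi = L - hi - 2 * self.m - 2
        if bound_hi <= bound_lo:
            return None
        for _ in range(200):
            if left_type == "proper":
                lo_i, hi_i = np.searchsorted(pool, [bound_lo, bound_hi])
                if hi_i <= lo_i:
                    return None
                a = int(pool[self.rng.integers(lo_i, hi_i)])
            else:
                a = int(self.rng.integers(bound_lo, bound_hi))
                if left_type == "sv" and not self._distal(chrom, a):
                    continue
            w_lo, w_hi = a + lo, a + hi
            if right_type == "proper":
                lo_i, hi_i = np.searchsorted(pool, [w_lo, w_hi + 1])
                if hi_i <= lo_i:
                    continue
                b = int(pool[self.rng.integers(lo_i, hi_i)])
            elif right_type == "sv":
                b = None
                for _ in range(30):
                    cand = int(self.rng.integers(w_lo, w_hi + 1))
                    if self._distal(chrom, cand):
                        b = cand
                        break
                if b is None:
                    continue
            else:
                b = int(self.rng.integers(w_lo, w_hi + 1))
            return a, b
        return None


def _zone_windows(n: int, lo: int, hi: int) -> list[tuple[int, int]]:
    if n == 0:
        return []
    if n == 1:
        return [(lo, hi)]
    mid = (lo + hi) // 2
    return [(lo, mid - 10), (mid + 10, hi)]


def _split_junctions(k: int, rng: np.random.Generator) -> tuple[int, int]:
    nj = k - 1
    if nj == 0:
        return 0, 0
    if nj == 1:
        return (1, 0) if rng.random() < 0.5 else (0, 1)
    if nj == 2:
        return 1, 1
    if nj == 3:
        return (2, 1) if rng.random() < 0.5 else (1, 2)
    return 2, 2


def _sample_molecule(
    config: SimConfig,
    sampler: _FragmentSampler,
    chrom_names: list[str],
    rng: np.random.Generator,
    k: int,
) -> list[tuple[str, str, int, int]] | None:
    """One molecule as a list of (chrom, strand, start, end) in molecule order."""
    rl = config.read_length
    z_lo, z_hi = _MARGIN, rl - 65
    lmol_lo, lmol_hi = 2 * rl - 60, 2 * rl - 20
    right_min = rl + 5

    k1, k2 = _split_junctions(k, rng)
    kinds = [
        "sv" if rng.random() < config.fraction_sv_junctions else "proper"
        for _ in range(k - 1)
    ]
    chroms = [chrom_names[rng.integers(len(chrom_names))]]
    for _ in range(k - 1):
        if len(chrom_names) > 1 and rng.random() < config.fraction_trans:
            others = [c for c in chrom_names if c != chroms[-1]]
            chroms.append(others[rng.integers(len(others))])
        else:
            chroms.append(chroms[-1])
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(k)]

    def end_types(i: int) -> tuple[str, str]:
        t5 = kinds[i - 1] if i > 0 else "free"
        t3 = kinds[i] if i < k - 1 else "free"
        return t5, t3

    fragments: list[tuple[int, int] | None] = [None] * k

    # right-side fragments (lengths are end-distances within the R2 zone)
    right_windows = _zone_windows(k2, z_lo, z_hi)
    r_total = 0
    for j in range(k2):
        i = k - 1 - j  # from the last fragment inwards
        w = right_windows[0] if j == 0 else right_windows[1]
        window = (w[0] - r_total, w[1] - r_total)
        t5, t3 = end_types(i)
        frag = sampler.sample(chroms[i], strands[i], window, t5, t3)
        if frag is None:
            return None
        fragments[i] = frag
        r_total += frag[1] - frag[0]

    # left-side fragments (junction positions within the R1 zone)
    left_windows = _zone_windows(k1, z_lo, z_hi)
    t_prev = 0
    for i in range(k1):
        w = left_windows[i]
        window = (w[0] - t_prev, w[1] - t_prev)
        t5, t3 = end_types(i)
        frag = sampler.sample(chroms[i], strands[i], window, t5, t3)
        if frag is None:
            return None
        fragments[i] = frag
        t_prev += frag[1] - frag[0]

    # middle fragment spans the region both mates share
    mid = k1
    lo = max(right_min - r_total, right_min - t_prev, lmol_lo - t_prev - r_total, 40)
    hi = lmol_hi - t_prev - r_total
    t5, t3 = end_types(mid)
    frag = sampler.sample(chroms[mid], strands[mid], (lo, hi), t5, t3)
    if frag is None:
        return None
    fragments[mid] = frag

    out = []
    for i in range(k):
        a, b = fragments[i]
        out.append((chroms[i], strands[i], a, b))
    return out, kinds


def _junction_side_coords(
    frag: FragmentTruth, side: str
) -> tuple[int, int]:
    """(boundary, 1-based proximal base) of a fragment's molecule-5'/3' end."""
    if side == "3p":
        if frag.strand == "+":
            return frag.end, frag.end
        return frag.start, frag.start + 1
    if frag.strand == "+":
        return frag.start, frag.start + 1
    return frag.end, frag.end


def _build_molecule_truth(
    read_id: str,
    placed: list[tuple[str, str, int, int]],
    kinds: list[str],
    config: SimConfig,
    index: CutSiteIndex,
    genome: dict[str, str],
    rng: np.random.Generator,
) -> MoleculeTruth:
    m = len(config.enzyme.motif)
    rl = config.read_length
    fragments: list[FragmentTruth] = []
    pos = 0
    for i, (chrom, strand, a, b) in enumerate(placed):
        fragments.append(FragmentTruth(i, chrom, a, b, strand, pos, pos + (b - a)))
        pos += b - a
    lmol = pos
    k = len(fragments)

    junctions: list[JunctionTruth] = []
    for j in range(k - 1):
        x, y = fragments[j], fragments[j + 1]
        t = x.mol_end
        end_a, base_a = _junction_side_coords(x, "3p")
        end_b, base_b = _junction_side_coords(y, "5p")
        overlap = m if (kinds[j] == "proper" and config.duplicate_motif_at_junction) else 0
        junctions.append(
            JunctionTruth(
                index=j,
                kind=kinds[j],
                mol_pos=t,
                chrom_a=x.chrom,
                pos_a=base_a,
                strand_a=x.strand,
                chrom_b=y.chrom,
                pos_b=base_b,
                strand_b=y.strand,
                overlap=overlap,
                visible_mate="R1" if t < rl else "R2",
                dist_a=index.nearest_distance(x.chrom, end_a),
                dist_b=index.nearest_distance(y.chrom, end_b),
            )
        )

    mol_seq_parts = []
    for f in fragments:
        part = genome[f.chrom][f.start : f.end]
        mol_seq_parts.append(part if f.strand == "+" else reverse_complement(part))
    mol_seq = "".join(mol_seq_parts)
    r1_seq = mol_seq[:rl]
    r2_seq = reverse_complement(mol_seq[lmol - rl :])

    records: list[RecordTruth] = []
    for mate, w0, w1 in (("R1", 0, rl), ("R2", lmol - rl, lmol)):
        mate_records: list[RecordTruth] = []
        for f in fragments:
            right_j = junctions[f.index] if f.index < k - 1 else None
            left_j = junctions[f.index - 1] if f.index > 0 else None
            ext = right_j.overlap if right_j is not None else 0
            p = max(f.mol_start, w0)
            q = min(f.mol_end + ext, w1)
            if q - p < 1:
                continue
            trim5 = (
                left_j.overlap
                if left_j is not None and left_j.visible_mate == mate
                else 0
            )
            trim3 = (
                right_j.overlap
                if right_j is not None and right_j.visible_mate == mate
                else 0
            )
            pt, qt = p + trim5, q - trim3

            def ref_span(p_: int, q_: int) -> tuple[int, int]:
                off5, off3 = p_ - f.mol_start, q_ - f.mol_start
                if f.strand == "+":
                    return f.start + off5, f.start + off3
                return f.end - off3, f.end - off5

            rs, re = ref_span(p, q)
            trs, tre = ref_span(pt, qt)
            if mate == "R1":
                read_span = (p, q)
                trimmed_read = (pt, qt)
                strand = f.strand
            else:
                read_span = (lmol - q, lmol - p)
                trimmed_read = (lmol - qt, lmol - pt)
                strand = "-" if f.strand == "+" else "+"
            mapq = (
                config.low_mapq_value
                if rng.random() < config.low_mapq_fraction
                else 60
            )
            mate_records.append(
                RecordTruth(
                    mate=mate,
                    frag_index=f.index,
                    chrom=f.chrom,
                    strand=strand,
                    ref_start=rs,
                    ref_end=re,
                    read_start=read_span[0],
                    read_end=read_span[1],
                    trimmed_ref_start=trs,
                    trimmed_ref_end=tre,
                    trimmed_read_start=trimmed_read[0],
                    trimmed_read_end=trimmed_read[1],
                    is_primary=False,
                    mapq=mapq,
                )
            )
        if mate_records:
            first = min(mate_records, key=lambda r: r.read_start)
            first.is_primary = True
        records.extend(mate_records)

    return MoleculeTruth(
        read_id=read_id,
        fragments=fragments,
        junctions=junctions,
        records=records,
        molecule_length=lmol,
        r1_seq=r1_seq,
        r2_seq=r2_seq,
    )


def simulate(config: SimConfig) -> Simulation:
    """Run the full simulation: genome, molecules, record-level truth."""
    rng = np.random.default_rng(config.seed)
    genome, index, motif_starts = simulate_genome(config, rng)
    sampler = _FragmentSampler(genome, index, motif_starts, config, rng)
    chrom_names = list(genome)
    ks = sorted(config.fragments_per_molecule)
    probs = np.asarray([config.fragments_per_molecule[k] for k in ks])
    probs = probs / probs.sum()
    molecules: list[MoleculeTruth] = []
    for i in range(config.n_read_pairs):
        k = int(rng.choice(ks, p=probs))
        placed = None
        for _ in range(100):
            placed = _sample_molecule(config, sampler, chrom_names, rng, k)
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(
                "could not place a molecule; genome too small or cut sites too "
                "sparse for the configured layout"
            )
        fragments, kinds = placed
        molecules.append(
            _build_molecule_truth(
                f"mol{i:06d}", fragments, kinds, config, index, genome, rng
            )
        )
    return Simulation(config, genome, index, motif_starts, molecules)


def _sam_header(sim: Simulation) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
            "SQ": [
                {"SN": chrom, "LN": length}
                for chrom, length in sim.chrom_lengths.items()
            ],
        }
    )


def iter_sam_records(sim: Simulation, header: pysam.AlignmentHeader | None = None):
    """Name-grouped pysam records for every molecule (primary + supplementary)."""
    if header is None:
        header = _sam_header(sim)
    tid = {chrom: i for i, chrom in enumerate(sim.chrom_lengths)}
    for mol in sim.molecules:
        primaries = {r.mate: r for r in mol.records if r.is_primary}
        for rec in sorted(mol.records, key=lambda r: (r.mate, not r.is_primary, r.read_start)):
            a = pysam.AlignedSegment(header)
            a.query_name = mol.read_id
            read_seq = mol.r1_seq if rec.mate == "R1" else mol.r2_seq
            L = len(read_seq)
            rs, re = rec.read_start, rec.read_end
            if rec.strand == "+":
                cig = [(4, rs), (0, re - rs), (4, L - re)]
                seq = read_seq
            else:
                cig = [(4, L - re), (0, re - rs), (4, rs)]
                seq = reverse_complement(read_seq)
            a.cigartuples = [(op, l) for op, l in cig if l > 0]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * L)
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.ref_start
            a.mapping_quality = rec.mapq
            flag = 0x1 | (0x40 if rec.mate == "R1" else 0x80)
            if rec.strand == "-":
                flag |= 0x10
            other = primaries.get("R2" if rec.mate == "R1" else "R1")
            if other is not None:
                if other.strand == "-":
                    flag |= 0x20
                a.next_reference_id = tid[other.chrom]
                a.next_reference_start = other.ref_start
            if not rec.is_primary:
                flag |= 0x800
            a.flag = flag
            yield a


def emit_sam(sim: Simulation, path: str) -> None:
    """Write the simulated alignments as a name-grouped SAM file."""
    header = _sam_header(sim)
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in iter_sam_records(sim, header):
            out.write(rec)


def write_fasta(sim: Simulation, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sim.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(sim: Simulation, path: str) -> None:
    """Flat truth table: fragment, junction and record rows per molecule."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\trow_type\tindex\tkind\tchrom_a\tpos_a\tstrand_a\t"
            "chrom_b\tpos_b\tstrand_b\toverlap\tvisible_mate\tdist_a\tdist_b\n"
        )
        for mol in sim.molecules:
            for f in mol.fragments:
                fh.write(
                    f"{mol.read_id}\tfragment\t{f.index}\t{f.strand}\t{f.chrom}\t"
                    f"{f.start}\t.\t{f.chrom}\t{f.end}\t.\t.\t.\t.\t.\n"
                )
            for j in mol.junctions:
                fh.write(
                    f"{mol.read_id}\tjunction\t{j.index}\t{j.kind}\t{j.chrom_a}\t"
                    f"{j.pos_a}\t{j.strand_a}\t{j.chrom_b}\t{j.pos_b}\t{j.strand_b}\t"
                    f"{j.overlap}\t{j.visible_mate}\t{j.dist_a}\t{j.dist_b}\n"
                )
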