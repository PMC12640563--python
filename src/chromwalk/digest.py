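"""In-silico restriction digestion of a reference genome.

Sticky-end proximity ligation joins restriction fragments, so the facing
ends of a genuine Hi-C contact coincide with restriction-enzyme (RE) cut
sites.  This module builds the genome-wide cut-site index those proximity
tests query: for each enzyme motif occurrence the cut position is recorded
as a 0-based *between-base* offset (a cut at position ``k`` separates bases
``k-1`` and ``k``), which makes distance queries against half-open alignment
boundaries exact with no off-by-one correction.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pysam

__all__ = [
    "EnzymeSpec",
    "CutSiteIndex",
    "KNOWN_ENZYMES",
    "digest",
    "digest_fasta",
    "find_motif_starts",
    "reverse_complement",
    "INFINITE_DISTANCE",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Sentinel distance returned for chromosomes without any cut site.
INFINITE_DISTANCE = 2**31


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif plus cut offset.

    ``cut_offset`` is the 0-based position of the cut *within* the motif on
    the displayed strand, e.g. DpnII (``^GATC``) has offset 0 and NlaIII
    (``CATG^``) has offset 4.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if len(motif) < 3:
            raise ValueError(f"enzyme motif must be >= 3 bp, got {motif!r}")
        if set(motif) - set("ACGT"):
            raise ValueError(f"enzyme motif must be over ACGT, got {motif!r}")
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside motif of length {len(motif)}"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.motif == reverse_complement(self.motif)


#: Common Hi-C enzymes, addressable by name from the CLI.
KNOWN_ENZYMES: dict[str, EnzymeSpec] = {
    "DpnII": EnzymeSpec("DpnII", "GATC", 0),
    "MboI": EnzymeSpec("MboI", "GATC", 0),
    "NlaIII": EnzymeSpec("NlaIII", "CATG", 4),
    "Csp6I": EnzymeSpec("Csp6I", "GTAC", 1),
    "HindIII": EnzymeSpec("HindIII", "AAGCTT", 1),
}


def find_motif_starts(seq: str, motif: str) -> list[int]:
    """0-based start positions of exact (case-insensitive) motif matches.

    Overlapping occurrences are reported; windows containing ``N`` (or any
    non-motif character) simply fail the exact comparison and are skipped.
    """
    seq = seq.upper()
    motif = motif.upper()
    starts: list[int] = []
    i = seq.find(motif)
    while i != -1:
        starts.append(i)
        i = seq.find(motif, i + 1)
    return starts


class CutSiteIndex:
    """Per-chromosome sorted arrays of cut positions with nearest-site queries."""

    def __init__(
        self,
        sites: Mapping[str, Iterable[int]],
        chrom_lengths: Mapping[str, int],
        enzymes: Sequence[EnzymeSpec] = (),
    ) -> None:
        if set(sites) - set(chrom_lengths):
            missing = sorted(set(sites) - set(chrom_lengths))
            raise ValueError(f"sites given for unknown chromosomes: {missing}")
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self.enzymes: tuple[EnzymeSpec, ...] = tuple(enzymes)
        self.sites: dict[str, np.ndarray] = {}
        for chrom, length in self.chrom_lengths.items():
            arr = np.unique(np.asarray(list(sites.get(chrom, ())), dtype=np.int64))
            if arr.size and (arr[0] < 0 or arr[-1] > length):
                raise ValueError(
                    f"cut site outside [0, {length}] on {chrom}: "
                    f"range {arr[0]}..{arr[-1]}"
                )
            self.sites[chrom] = arr

    @property
    def default_sv_tolerance(self) -> int | None:
        """Motif length + 1: sticky-end fill-in can shift an observed junction
        by up to the overhang length, so this is the widest shift a proper
        ligation end can show.  ``None`` when enzyme provenance is unknown."""
        if not self.enzymes:
            return None
        return max(len(e.motif) for e in self.enzymes) + 1

    def n_sites(self) -> int:
        return int(sum(a.size for a in self.sites.values()))

    def _chrom_sites(self, chrom: str) -> np.ndarray:
        try:
            return self.sites[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in cut-site index") from None

    def is_cut_site(self, chrom: str, pos: int) -> bool:
        arr = self._chrom_sites(chrom)
        i = np.searchsorted(arr, pos)
        return bool(i < arr.size and arr[i] == pos)

    def nearest_distance(self, chrom: str, pos: int) -> int:
        """Distance (bp, >= 0) from ``pos`` to the nearest cut site on ``chrom``.

        Returns :data:`INFINITE_DISTANCE` if the chromosome has no sites.
        """
        arr = self._chrom_sites(chrom)
        if arr.size == 0:
            return INFINITE_DISTANCE
        i = int(np.searchsorted(arr, pos))
        best = INFINITE_DISTANCE
        if i < arr.size:
            best = int(arr[i] - pos)
        if i > 0:
            best = min(best, int(pos - arr[i - 1]))
        return best

    def nearest_distances(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        arr = self._chrom_sites(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if arr.size == 0:
            return np.full(positions.shape, INFINITE_DISTANCE, dtype=np.int64)
        idx = np.searchsorted(arr, positions)
        right = np.where(idx < arr.size, arr[np.minimum(idx, arr.size - 1)] - positions, INFINITE_DISTANCE)
        left = np.where(idx > 0, positions - arr[np.maximum(idx - 1, 0)], INFINITE_DISTANCE)
        return np.minimum(right, left)

    @classmethod
    def from_bed(cls, path: str, chrom_lengths: Mapping[str, int]) -> "CutSiteIndex":
        """Load a precomputed cut-site BED (0-based, single-position intervals)."""
        sites: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                chrom, start = fields[0], int(fields[1])
                sites.setdefault(chrom, []).append(start)
        return cls(sites, chrom_lengths)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_lengths:
                for pos in self.sites[chrom]:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def digest(
    genome: Mapping[str, str], enzymes: Sequence[EnzymeSpec] | EnzymeSpec
) -> CutSiteIndex:
    """Digest ``genome`` (chrom -> sequence) with one or more enzymes.

    Palindromic motifs are scanned once on the forward strand.  For
    non-palindromic motifs the reverse-complement occurrence at forward
    position ``p`` cuts at ``p + len(motif) - cut_offset``.  Site sets of
    multiple enzymes are merged into one index.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    if not genome:
        raise ValueError("empty genome: no sequences to digest")
    sites: dict[str, set[int]] = {chrom: set() for chrom in genome}
    for chrom, seq in genome.items():
        for enz in enzymes:
            for p in find_motif_starts(seq, enz.motif):
                sites[chrom].add(p + enz.cut_offset)
            if not enz.is_palindromic:
                rc = reverse_complement(enz.motif)
                for p in find_motif_starts(seq, rc):
                    sites[chrom].add(p + len(enz.motif) - enz.cut_offset)
    lengths = {chrom: len(seq) for chrom, seq in genome.items()}
    return CutSiteIndex(sites, lengths, enzymes)


def digest_fasta(
    path: str, enzymes: Sequence[EnzymeSpec] | EnzymeSpec
) -> CutSiteIndex:
    """Digest a reference FASTA (plain or bgzipped) from disk."""
    genome: dict[str, str] = {}
    with pysam.FastaFile(path) as fa:
        for chrom in fa.references:
            genome[chrom] = fa.fetch(chrom)
    return digest(genome, enzymes)
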