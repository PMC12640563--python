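# Methods

## Scope and data model

chromwalk consumes name-grouped SAM/BAM from a soft-clipping local aligner.
Chimeric ligation products appear as several records per mate (one primary
plus supplementary records); secondary (0x100) and duplicate (0x400) records
are dropped, supplementary (0x800) records are kept — the encoding the
BWA-MEM family uses for split reads. Bisulfite-aligner output (Biscuit,
BSBolt) is handled identically, since the contract operates at the alignment
level; aligner-specific tags pass through untouched.

Every record is converted to a span on the **original read as sequenced**.
SAM reports clips in reference orientation, so for minus-strand records the
leading/trailing clip lengths are flipped; hard-clipped bases count into the
read length so that coordinates agree across supplementary records of one
read. All internal coordinates are 0-based half-open; conversion to the
pairs format's 1-based positions (and BEDPE's 0-based intervals) happens
only at serialization, so there is a single conversion boundary.

## Restriction map

Cut positions are stored as 0-based *between-base* offsets: a cut at `k`
separates bases `k-1` and `k`. This makes a cut position directly comparable
to a half-open alignment boundary with no off-by-one correction, which is
why facing-end distances of perfect ligation events are exactly zero.
Palindromic motifs are scanned once on the forward strand; non-palindromic
motifs are scanned on both strands (reverse-strand occurrence at `p` cuts at
`p + |motif| - cut_offset`) and the site sets merged. Multiple enzymes merge
into one index — the conservative superset. Matching is case-insensitive and
exact, so windows containing `N` never match. Degenerate (IUPAC) motifs and
methylation-sensitive digestion are out of scope; for enzymes with ambiguous
recognition sequences a precomputed cut-site BED can be supplied instead.
The assay's enzyme is required user input — it cannot be inferred from the
alignments.

## MAPQ filtering

Segments with `mapq < min_mapq` are removed before any downstream step.
The default `min_mapq = 30` is the conventional "unique alignment" cutoff
for BWA-MEM-derived MAPQ scales; it is user-configurable and removal counts
are reported in QC.

## Multimapping trimming

Sticky-end ligation leaves one restriction motif at a junction; because both
flanking loci border that motif in the reference, the aligner maps the
junction bases into both adjacent alignments of the read. The motif can only
derive from one locus in vivo, and there is no evidence to assign it to
either side, so the overlap is removed from **both** segments: the upstream
segment loses the overlapping aligned bases at its 3'-in-read end, the
downstream at its 5'-in-read end. Trimming operates on read-coordinate
overlap generically rather than matching the motif text, because other
local-realignment artifacts produce the same signature.

CIGAR rewriting walks ops inward from the trimmed end: removed
query-consuming ops convert into soft clip (merged with any existing clip,
preserving the `H S core S H` layout); reference-consuming ops walked over
shrink the reference span on the strand-appropriate side; deletions (D/N)
stranded at the new alignment edge are dropped. A segment fully consumed by
an overlap is removed from the chain and counted. The procedure iterates
until all spans of a chain are pairwise disjoint, and is idempotent.
Trimming runs **before** contact and breakpoint calling, so junction
coordinates never carry the duplicated motif (which would shift them by up
to `|motif|` bp). Note that symmetric removal converts a duplicated-motif
junction into a `|motif|`-bp read gap, so trimmed sticky-end junctions are
classified `gapped` rather than `adjacent_softclip`; SV junctions have no
duplicated motif and remain exactly abutting.

Per-segment statistics record the original aligned span and the bases
trimmed; the trimmed fraction is `trimmed / original aligned span`, and the
QC mean/std are taken over soft-clipped segments that had multimapping
(segments removed outright contribute fraction 1).

Rewritten records keep their original SEQ/QUAL (soft clips absorb the
removal) and tags; alignment-dependent tags such as NM/MD are not
recomputed.

## Contact calling

**mask** emits at most one two-locus contact per read pair: `UU` for plain
1+1 pairs; for 2+1 pairs, if the chimeric mate's 3'-in-read segment is the
other mate's view of the same fragment end (same chromosome, opposite
strand, 5' positions within the rescue window), the pair is *rescued*
(`RU`/`UR`) and the contact joins the two 5'-in-read segments. Anything more
complex is masked (`MM`); missing mates give `N` codes. **all** reconstructs
the full walk — R1's chain in read order, R2's chain in reverse read order,
merging the two mates' duplicated terminal fragment under the same matching
rule — and emits one contact per consecutive walk pair, indexed along the
walk. A 1+1 pair gives identical output under both policies; a self-ligation
pair collapses to a single-locus walk and no contact.

The rescue window defaults to 500 bp, an upper bound on typical restriction
fragment spans; positions are the 5'-in-read reference coordinates
(`ref_start+1` on `+`, `ref_end` on `-`), the standard pairs convention.
Contacts are canonicalized to upper-triangle order (header chromosome order,
then position); strands, pair-type characters and cut-site distances swap
together with the sides. PCR/optical duplicate removal is deliberately not
performed — the PAIRS output is position-sorted so standard downstream dedup
tools apply directly.

## SV annotation and breakpoints

For a within-mate junction the facing ends are the upstream segment's
3'-in-read terminus (`ref_end` on `+`, `ref_start` on `-`) and the
downstream segment's 5'-in-read terminus (mirrored); for mate-paired
contacts, whose junction lies in the unsequenced middle of the molecule,
both 3'-in-read termini face the junction. Distances to the nearest cut site
are recorded on every contact; the SV flag is raised when **either**
distance exceeds the tolerance (a single distal end already violates the
digestion model; both distances are emitted so users can impose an AND
rule). The default tolerance is `|motif| + 1` bp because sticky-end fill-in
and symmetric trimming can shift an observed proper-junction end by up to
the overhang length. Mate-paired facing ends are generally *not* at cut
sites (the read stops wherever its length runs out), so the flag on
mate-paired contacts is only meaningful with a user-widened tolerance; the
base-resolution claims below concern read-through junctions only. For a
rescued mask contact the annotation uses the chimeric mate's read-through
junction, whose downstream flank is the same fragment end as the reported
mate segment.

Breakpoints are called per mate chain: every read-adjacent pair with
`gap <= max_junction_gap` (default 0 — unread junction bases forfeit the 1 bp
claim) whose facing ends are distal yields a breakpoint at the two
junction-proximal bases, intra- or interchromosomal. No cross-read
clustering is performed in the caller; the BEDPE writer aggregates support
per unique junction and QC reports the support table.

## Simulator

The simulator is the package's test bed. It generates a uniform-random
genome (default 3 chromosomes x 300 kb), digests it, and builds ligation
products of 1–5 fragments. Proper junctions join fragments whose boundaries
sit at motif occurrences (shifted by `|motif|` for minus-strand fragments so
each fragment's molecule-oriented sequence begins with the motif); with
`duplicate_motif_at_junction` the single junction motif is emitted inside
both flanking alignments, planting a known overlap of exactly `|motif|`
read bases. SV junctions join fragments at coordinates at least
`sv_distal_distance[0]` (default 50) bp from any cut site, with the exact
junction bases recorded as truth. Trans junctions occur at
`fraction_trans` (default 0.2).

Molecules are laid out deterministically relative to the mate windows: the
two 150 bp reads tile the molecule (length `2*rl - 60 … 2*rl - 20`) with a
20–60 bp overlap inside a single shared middle fragment, and every junction
falls at least 25 bp inside exactly one mate's window. This is the
configuration in which the complete walk is recoverable and each junction is
observed exactly once — the regime the recovery guarantees are stated for.
The truth table stores per-record nominal and expected post-trim spans, so
tests can compare pipeline output to planted values exactly.

Not emulated: sequencing errors, base-quality variation, bisulfite
conversion, PCR duplicates, repetitive sequence and the mapping ambiguity it
causes, random soft-clipping unrelated to junctions, and molecules whose
interior fragments are unsequenced. Consequently passing tests demonstrate
the correctness of the coordinate arithmetic, trimming, walk reconstruction
and annotation logic — not robustness to alignment noise; on real data,
MAPQ filtering is the guard against the latter. Because every soft clip in
simulated data borders a junction, simulated multimapping prevalence
(~100% of soft-clipped alignments when motif duplication is on) is higher
than the 25–30% seen in real libraries.

The simulator requires `read_length >= 110` (layout margins) and, for motif
duplication, a palindromic motif — true of the common Hi-C enzymes
(DpnII/MboI GATC, NlaIII CATG). Defaults: DpnII-like GATC with cut offset 0.

## QC

`cis` means same chromosome, with no distance cutoff. The cis/trans ratio is
reported `None` (JSON null) when there are no trans contacts. The pair-type
histogram counts one code per read pair in emission orientation (the
serialized pairs rows may carry the mirrored code when canonicalization
swapped sides). Aggregation is per cell; `qc-merge` tabulates multiple
report files with mean/std summary rows.

## Verification protocol and problem sizes

The acceptance tests run, per property: 100 x 10 kb digestion oracles
(4-mer and 6-mer motifs), 1,000 randomized CIGAR round-trips, 10,000
duplicated-motif junctions for trimming, 5,000 mixed walks for both contact
policies against brute-force enumerators, 2,000 junctions in a 50/50
proper/SV mixture (>= 50 bp distal, 5 bp tolerance) for breakpoint recall,
and 10,000 contacts on a 4:1 cis/trans design (checked within 3 binomial
standard errors). `scripts/acceptance.py` re-measures the same quantities on
fresh simulations from a user seed. These sizes give stable statistics while
keeping a full run in the tens of seconds on one CPU.
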