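# chromwalk

Processing engine for **multiomic single-cell Hi-C** alignments: from the
name-grouped, soft-clipped records a local aligner (BWA-MEM family, or the
bisulfite aligners built on it) produces for proximity-ligation reads,
chromwalk derives

* **chromatin contacts** under a two-locus ("mask") or a multi-locus walk
  ("all") policy, written as a 4DN PAIRS file;
* **multimapping-trimmed alignments**: sticky-end ligation leaves a single
  restriction motif at each junction, which aligners map redundantly into
  both flanking alignments of the read — chromwalk removes the duplicated
  read bases from both sides and rewrites the CIGARs, emitting a trimmed BAM;
* **restriction-site proximity annotations**: each contact carries the
  distances of its facing alignment ends to the nearest in-silico cut site;
  contacts distal from cut sites violate the digestion/ligation model and are
  flagged as likely induced by structural variants (SVs);
* **1 bp SV breakpoints**: when a flagged junction is read through — two
  adjacent soft-clipped alignments abutting on the read — the junction
  coordinates pin the breakpoint at single-base resolution (BEDPE output,
  intra- and interchromosomal alike);
* **QC metrics** per cell, including the cis/trans contact ratio and
  junction-trimming statistics.

It is written for people processing single-cell Hi-C and multiomic variants
(e.g. methylome + conformation or transcriptome + conformation assays) who
need clean contact lists, artifact-free alignments and base-resolution SV
candidates from the same run.

## The model in brief

A sequenced molecule is a *walk* `L_1 — L_2 — … — L_k` of ligated genomic
loci. Each mate's alignments are ordered by their spans on the original read;
the full walk is R1's chain followed by R2's chain in reverse read order,
merging the terminal fragment both mates share. Contacts are consecutive
locus pairs of the walk; reported positions follow the pairs convention
(5'-in-read reference coordinate: `ref_start + 1` on `+`, `ref_end` on `-`).

For a junction between read-adjacent alignments, the *facing ends* are the
upstream segment's 3'-in-read terminus and the downstream segment's
5'-in-read terminus. In a proper sticky-end ligation product these coincide
with restriction cut sites up to the overhang fill-in shift, so the default
proximity tolerance is `|motif| + 1` bp. A junction whose facing-end
distance exceeds the tolerance on either side is SV-flagged, and if
its flanks abut on the read (`gap = 0`), the two facing-end coordinates are
emitted as a 1 bp breakpoint.

## Worked example

chromwalk ships a simulator that generates a random genome, in-silico
ligation products (including the duplicated junction motif and planted SV
junctions with known coordinates) and aligner-style SAM with a truth table:

```sh
cat > sim.toml <<'EOF'
seed = 7
n_read_pairs = 500
fraction_sv_junctions = 0.15
EOF
chromwalk simulate --config sim.toml --out-prefix sim
chromwalk call --bam sim.sam --fasta sim.fa --enzyme DpnII \
    --policy all --out-prefix out
```

which logs

```
chromwalk INFO digested index: 3470 cut sites
chromwalk INFO 500 read pairs -> 710 contacts, 107 breakpoints
```

and writes `out.trimmed.bam`, `out.pairs`, `out.breakpoints.bedpe`,
`out.qc.json` and `out.qc.tsv`. Key fields of `out.qc.json`:

```
total_read_pairs                500
softclipped_segments            1320
softclipped_with_multimapping   1123
trimmed_fraction_mean           0.0728
contacts_total                  710
cis_trans_ratio                 3.83
sv_flagged_contacts             107
breakpoints_total               107
```

Read: of 1320 soft-clipped alignments, 1123 carried junction multimapping,
and trimming removed on average 7.3% of their aligned read spans; the run
yielded 710 contacts at a cis/trans ratio of 3.8 (the simulation generates
trans junctions at 20% frequency), and all 107 SV-flagged read-through
junctions were resolved to 1 bp breakpoints, e.g.

```
chr1    9149    9150    chr1    47675   47676   mol000250   1   -   -
```

a BEDPE row giving both breakpoint bases (0-based half-open), the supporting
read and the junction strands. Against the simulator's truth table these
breakpoints are exact to the base.

A cohort of per-cell QC reports can be tabulated with
`chromwalk qc-merge cellA.qc.json cellB.qc.json --out summary.tsv`.

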