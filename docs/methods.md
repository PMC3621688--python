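# Methods

## Coordinate model

All coordinates inside the package are 0-based half-open. The 1-based
conventions of GFF3 (inclusive) and SAM (`POS`, relation intervals) are
converted exactly once, at the parse/serialize boundary in `formats`; no other
module performs ±1 arithmetic. SAM optional tags are carried as opaque
`(tag, type, value)` string triples, which is what makes
`write_sam(read_sam(x))` byte-identical for valid input; only `AS:i` is ever
interpreted (as the alignment score during paralog resolution).

## Region extraction

A gene `[gene_start, gene_end)` on chromosome of length `L` with strand `s`
becomes the region

```
s = "+":  [max(0, gene_start − up),   min(L, gene_end + down))
s = "−":  [max(0, gene_start − down), min(L, gene_end + up))
```

with `up = flank_upstream` (default 500 bp, anchored at the TSS) and
`down = flank_downstream` (default 500 bp, at the 3′ end). Truncation at
chromosome boundaries is silent, matching coordinate clamping in comparable
liftover tools. Extracted sequences are **always forward genomic strand**,
never reverse-complemented: the long-sequence aligner detects orientation, so
the whole pipeline carries exactly one orientation flag (the alignment's
`0x10` bit), halving the strand algebra. The gene strand is recorded in the
header only as provenance. Unstranded features (`.`) are treated as `+` with a
warning — the flank anchors assume a transcript direction, and a deterministic
fallback beats a hard failure. Overlapping genes yield overlapping regions;
nothing is merged. Which GFF3 feature type is consumed is a config knob
(`feature_type`, default `gene`) so mRNA-level annotations work unchanged.

## Paralog resolution

Within each gene: candidates failing every user preference for that gene are
discarded (genes without preferences keep everything), then one survivor is
chosen under the total order *(score desc, target name asc, target start asc,
input position asc)*. Score is `AS:i` when present, else the sum of M/=/X
lengths. Secondary (0x100) and supplementary (0x800) records are dropped
first — they duplicate the primary's gene sequence. The optional reciprocal
filter then greedily accepts survivors in the same total order, rejecting any
whose target span overlaps an accepted one on the same sequence by more than
50 % of the shorter span; this is a deterministic, testable instantiation of
"keep only reciprocally unique loci", with the threshold fixed rather than
exposed. The total order makes the whole stage invariant under input
permutation, which the tests verify exhaustively on small instances.

## Coordinate maps

A gene alignment's CIGAR is walked with a target cursor (from `POS`) and a
clip-inclusive offset `i` into the stored sequence. Since the extracted
region is forward-strand, query position is `region_start + i` for forward
alignments; for reverse alignments the stored SEQ is the reverse complement of
the region, so offset `i` corresponds to `region_start + region_length − 1 − i`,
and each M run becomes a block whose smallest query position pairs with its
largest target position (pairing proceeds downward). M/=/X emit blocks; I/S/H
advance only the offset; D/N advance only the target (an intron skip and a
deletion are indistinguishable for coordinate lifting, so N ≡ D). The full
clip-inclusive CIGAR must account for exactly `region_length` bases, otherwise
the alignment does not belong to its header's region and the map is refused.
Adjacent blocks contiguous on both genomes are merged. Maps persist as a
7-column TSV, one block per line — lossless and compact compared to per-base
listing. Lookup uses an `intervaltree` per query chromosome over map spans;
positions in inter-block gaps (query-lineage insertions) lift to nothing.

## Read conversion

`choose_map` arbitrates overlapping gene regions: the map lifting the largest
number of the read's aligned bases wins, ties to the smaller gene id, and a
best count below `min_mapped_bases` (default 1) means unmapped. Composition is
evaluated per read base: lifted bases emit M, in-span unlifted bases emit I,
out-of-span bases become end soft clips (they can only occur at the ends,
since aligned positions are monotone and the span is an interval), the read's
own I/S pass through, and D operations materialize as the jump between
consecutive lifted target positions — which uniformly handles the read's own
deletions, the map's target-side insertions, and their combinations, and
silently drops deletions whose positions do not lift. For reverse maps the
per-base event list is reversed before assembly and the record's strand bit is
toggled, SEQ reverse-complemented, QUAL reversed. Two edge policies are the
package's own: (1) insertion bases adjacent to the alignment ends after
composition are emitted as soft clips, because a CIGAR beginning or ending in
I fails strict SAM validation; (2) when a previously reverse-strand read is
marked unmapped, its strand bit is cleared and SEQ/QUAL restored to original
orientation, keeping the stored sequence consistent with the flags (samtools
convention).

Mate fields (`RNEXT/PNEXT/TLEN`) are reset and the proper-pair bit cleared on
every output record — mates may lift through different genes, so preserving
linkage would assert something unverified; 0x1/0x40/0x80 are retained. `MD`
and `NM` are dropped rather than recomputed: they describe mismatches against
the *query* genome and would be wrong in target coordinates, while
recomputation would require target-sequence comparison, a non-goal. The
output header carries `@SQ` for every target-genome sequence and a fixed `@PG`
line with no timestamp or argv, so repeated runs are byte-identical. With
`n_jobs > 1` the input splits into contiguous chunks processed independently
and concatenated in order; the output is byte-identical to a serial run, which
replaces cluster-scheduler parallelism with the same contract and no
infrastructure.

## Simulator

`synthetic` emulates a closely related species pair: per-base mutually
exclusive events (substitution 1 %, insertion 0.2 %, deletion 0.2 %, indel
lengths uniform on 1–10 bp) applied left to right, recording every surviving
base's coordinate pair in an exact `TruthMap`. Defaults: two 50 kb
chromosomes, 20 genes of 500–1500 bp separated by ≥ 1200 bp (so 500 bp-flanked
regions never overlap and 20 genes pack into 100 kb), 5000 error-free 75 bp
reads with exact all-M alignments, 20 % of them drawn wholly outside every
region to exercise the unmapped path, random strands stored as an aligner
would (reverse-complemented, flag 0x10). Gene-to-target "alignments" are
constructed directly from the truth map (corresponding runs → M, query-only →
I, target-only → D, region-end query-only runs → S), standing in for the
external aligner with zero alignment error.

What the simulation deliberately omits — sequencing errors, quality models,
read-mapping ambiguity, structural rearrangements, exon/intron structure,
repeat-induced mis-alignment of the gene regions — bounds what passing tests
show: they verify that *given correct gene alignments* the coordinate algebra
is exact to the base, not that an aligner will produce correct alignments on
diverged or repetitive real genomes. On real data the accuracy of the lift is
inherited from the long-sequence aligner.

## Numerical / degenerate-input choices

Tie-breaks are total everywhere randomness could leak in (resolution order,
map choice), so every stage is a pure function of its inputs. Degenerate
cases: empty read SAM → header-only output; a gene region fully deleted in the
target → no alignment record, its reads become unmapped; `flank = 0` is legal
(flankless extraction); a 1-base genome under deletion rate 1 produces an
empty target chromosome and an empty truth map. Mutation-rate validation
allows event-probability sums up to 1 so such deterministic degenerate
configurations remain expressible.

## Known limitations

One map per read: a read straddling two gene regions is clipped to the better
one, never split. Paired-end linkage is not reconstructed. No BAM/CRAM, no
coordinate sorting, no recomputation of mismatch tags, no chain/net
interchange. Genome-free query species are supported only implicitly: any
FASTA (e.g. assembled transcripts, one contig per "chromosome") can serve as
the query genome.
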