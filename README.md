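# readlift

Cross-species coordinate liftover for aligned sequencing reads.

When RNA-seq or ChIP-seq reads from one species (the *query*, often a
non-model organism) are to be compared with data from a related species (the
*target*), the reads' mapping coordinates must be transformed between the two
genomes. Aligning the reads directly to the target genome is fragile —
polymorphisms between the species break short-read alignment exactly where the
comparison is interesting — and BED-centric liftover tools cannot carry SAM
records. `readlift` instead aligns *long* gene-region sequences between the
genomes once, turns those alignments into base-level coordinate maps, and
rewrites every read's RNAME/POS/FLAG/CIGAR (reverse-complementing SEQ when the
orientation flips) into valid target-coordinate SAM that any read-aware genome
browser can display. Reads on non-corresponding positions are marked unmapped.

## How it works

1. **extract** — for every gene in the query GFF3, cut the forward-strand
   genomic sequence of the gene plus strand-aware flanks (default 500 bp
   upstream of the TSS and 500 bp downstream of the 3′ end) into a FASTA whose
   headers encode provenance: `<gene_id>::<chrom>:<start>-<end>(<strand>)`
   (0-based half-open).
2. *(external)* — align that FASTA to the target genome with a long-sequence
   aligner (e.g. GMAP; BLAST/BLAT output must be converted to SAM). This is an
   input contract, not part of the package.
3. **resolve** — paralogs make the gene↔target relation one-to-many; keep at
   most one alignment per gene, preferring user-stated gene→target relations,
   then the alignment score (`AS` tag, with an aligned-base-count fallback),
   under a total tie-break order so the choice is reproducible.
4. **combine** — walk each surviving alignment's CIGAR into colinear blocks
   pairing query positions `q` with target positions `t(q) = t₀ ± (q − q₀)`
   (`+` for forward, `−` for reverse-strand alignments), indexed per query
   chromosome for interval lookup.
5. **convert** — for each read, choose the map explaining the most aligned
   bases and compose the read's CIGAR with the map: lifted bases stay `M`,
   query-lineage insertions become `I`, target-side jumps become `D`, bases
   outside the map become soft clips, and reads with no lifted base are
   flagged unmapped (`0x4`).

A built-in simulator (`readlift simulate`) generates a query genome, a mutated
sister genome with an exact base-level truth map, annotations, pre-aligned
reads and truth-derived gene alignments, so the whole pipeline can be
exercised and verified without any external data or aligner.

## Worked example

```sh
readlift simulate --out-dir demo --seed 42
readlift run-all --config demo/settings.ini
```

prints (to stderr):

```
INFO readlift: extracted 20 regions to demo/regions.fa
INFO readlift.convert: converted 5000 reads: 3978 transformed, 1022 newly unmapped, 0 passthrough
INFO readlift: pipeline complete: 5000 reads, 3978 transformed, 1022 unmapped, output demo/converted.sam
```

The simulation placed 20 genes on two 50 kb chromosomes and drew 5000 × 75 bp
reads, one fifth of them deliberately outside every gene region. All reads
inside regions (3978 here) are rewritten into the mutated sister genome's
coordinates — every `M` base landing exactly where the simulation's truth map
says its query base corresponds — and the reads outside any mapped region come
out flagged unmapped. `demo/converted.sam` carries `@SQ` lines for the target
genome and loads directly in IGV-style browsers.

Real data uses the same `settings.ini`, pointing at your reads SAM, query
genome FASTA + GFF3, target genome FASTA, and the gene-region alignment SAM
from step 2.

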