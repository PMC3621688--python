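"""Independent brute-force oracles used across the test suite.

Everything here enumerates per-base (query, target) pairs one base at a
time, deliberately ignoring the block structures and composition shortcuts
of the package under test.
"""

from __future__ import annotations

from typing import Optional

from readlift.coordmap import FORWARD, REVERSE, CoordinateMap, MapBlock
from readlift.formats import SamRecord
from readlift.regions import GeneRegion


def alignment_base_pairs(
    record: SamRecord, region: GeneRegion
) -> list[tuple[int, int]]:
    """Per-base (query_pos, target_pos) pairs of a gene-region alignment.

    Walks the CIGAR one base at a time.  The stored sequence is the region
    forward strand, or its reverse complement when flag 0x10 is set, in
    which case clip-inclusive stored offset i corresponds to region offset
    region_length - 1 - i.
    """
    L = region.region_length
    pairs = []
    i = 0  # clip-inclusive stored-sequence offset
    t = record.pos
    for op in record.cigar or []:
        for _ in range(op.length):
            if op.code in "M=X":
                if record.is_reverse:
                    q = region.region_start + L - 1 - i
                else:
                    q = region.region_start + i
                pairs.append((q, t))
                i += 1
                t += 1
            elif op.code in "ISH":
                i += 1
            elif op.code in "DN":
                t += 1
    return sorted(pairs)


def map_base_pairs(cmap: CoordinateMap) -> list[tuple[int, int]]:
    """All (query, target) pairs a coordinate map encodes, expanded."""
    pairs = []
    for b in cmap.blocks:
        for k in range(b.length):
            if cmap.orientation == FORWARD:
                pairs.append((b.query_start + k, b.target_start + k))
            else:
                pairs.append((b.query_start + k, b.target_start - k))
    return sorted(pairs)


def read_query_positions(read: SamRecord) -> dict[int, int]:
    """stored-base index → query position for the read's M/=/X bases."""
    out = {}
    i = 0
    q = read.pos
    for op in read.cigar or []:
        if op.code in "M=X":
            for _ in range(op.length):
                out[i] = q
                i += 1
                q += 1
        elif op.code in "IS":
            i += op.length
        elif op.code in "DN":
            q += op.length
    return out


def output_target_positions(record: SamRecord) -> dict[int, int]:
    """stored-base index → target position implied by (POS, CIGAR)."""
    out = {}
    i = 0
    t = record.pos
    for op in record.cigar or []:
        if op.code in "M=X":
            for _ in range(op.length):
                out[i] = t
                i += 1
                t += 1
        elif op.code in "IS":
            i += op.length
        elif op.code in "DN":
            t += op.length
    return out


def composed_read_pairs(
    read: SamRecord, lift, flipped: bool
) -> set[tuple[int, int]]:
    """Brute-force (stored-output-index, target) pairs for liftable bases.

    *lift* maps a query position to a target position or None; *flipped*
    says whether the output record stores the read in the opposite
    orientation, re-indexing base i as len(seq)-1-i.
    """
    L = len(read.seq)
    pairs = set()
    for i, q in read_query_positions(read).items():
        t = lift(q)
        if t is None:
            continue
        j = L - 1 - i if flipped else i
        pairs.add((j, t))
    return pairs


def invert_map(cmap: CoordinateMap) -> CoordinateMap:
    """Swap the query and target roles of a coordinate map, per base."""
    swapped = sorted((t, q) for q, t in map_base_pairs(cmap))
    blocks: list[MapBlock] = []
    run: list[tuple[int, int]] = []
    step = 1 if cmap.orientation == FORWARD else -1
    for q, t in swapped:
        if run and q == run[-1][0] + 1 and t == run[-1][1] + step:
            run.append((q, t))
            continue
        if run:
            blocks.append(MapBlock(run[0][0], run[0][1], len(run)))
        run = [(q, t)]
    if run:
        blocks.append(MapBlock(run[0][0], run[0][1], len(run)))
    return CoordinateMap(
        gene_id=cmap.gene_id,
        query_chrom=cmap.target_chrom,
        target_chrom=cmap.query_chrom,
        orientation=cmap.orientation,
        blocks=blocks,
    )
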