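"""Block-structured query→target coordinate maps built from gene alignments.

Each resolved gene-region alignment is turned into a list of colinear blocks
pairing query-genome positions with target-genome positions.  Within a
block the correspondence is affine: forward maps send ``q`` to
``target_start + (q - query_start)``; reverse maps (gene region aligned to
the opposite target strand) send ``q`` to ``target_start - (q - query_start)``,
i.e. ``target_start`` is paired with the block's smallest query position and
pairing proceeds downward.

Blocks are maximal runs of matched bases: substitutions stay inside a
block, while indels (CIGAR I/D/N and clipped flanks) break blocks apart.
Query positions between two blocks — bases of the query lineage with no
target partner — lift to nothing.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .formats import FormatError, SamRecord
from .homology import ScoredAlignment
from .regions import GeneRegion

__all__ = [
    "MapBlock",
    "CoordinateMap",
    "MapIndex",
    "build_coord_map",
    "build_index",
    "lift_position",
    "save_maps",
    "load_maps",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class MapBlock:
    query_start: int
    target_start: int
    length: int

    def target_of(self, q: int, orientation: str) -> int:
        offset = q - self.query_start
        if orientation == FORWARD:
            return self.target_start + offset
        return self.target_start - offset


@dataclass
class CoordinateMap:
    """All colinear blocks of one gene region's alignment to the target."""

    gene_id: str
    query_chrom: str
    target_chrom: str
    orientation: str  # "forward" or "reverse"
    blocks: list[MapBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks.sort(key=lambda b: b.query_start)
        self._starts = [b.query_start for b in self.blocks]

    @property
    def query_span(self) -> tuple[int, int]:
        """Smallest half-open query interval covering all blocks."""
        if not self.blocks:
            return (0, 0)
        first, last = self.blocks[0], self.blocks[-1]
        return (first.query_start, last.query_start + last.length)

    def lift(self, q: int) -> Optional[int]:
        """Target position paired with query position *q*, or None."""
        i = bisect_right(self._starts, q) - 1
        if i < 0:
            return None
        block = self.blocks[i]
        if q < block.query_start + block.length:
            return block.target_of(q, self.orientation)
        return None


def build_coord_map(aln: ScoredAlignment, region: GeneRegion) -> CoordinateMap:
    """Convert one gene-region alignment into a coordinate map.

    The extracted region sequence is forward genomic strand, so the region
    offset of an aligned base recovers its query-genome position directly
    for a forward alignment.  For a reverse alignment (flag 0x10) the
    stored SEQ is the reverse complement of the region, and stored offset
    ``i`` (counting clips) corresponds to region offset
    ``region_length - 1 - i``.

    Clips (S and H) shrink the covered span; I advances only the sequence
    cursor, D/N only the target cursor.  The full clip-inclusive CIGAR must
    account for exactly ``region_length`` query bases.
    """
    rec = aln.record
    if rec.cigar is None:
        raise FormatError(f"alignment {rec.qname} has no CIGAR")
    consumed = sum(op.length for op in rec.cigar if op.code in "MIS=XH")
    if consumed != region.region_length:
        raise FormatError(
            f"alignment {rec.qname}: CIGAR accounts for {consumed} query bases "
            f"but the region has {region.region_length}"
        )
    reverse = rec.is_reverse
    L = region.region_length
    blocks: list[MapBlock] = []
    i = 0  # clip-inclusive offset in the stored sequence orientation
    t = rec.pos
    for op in rec.cigar:
        if op.code in "M=X":
            if reverse:
                # stored offsets [i, i+len) pair with targets [t, t+len);
                # region offset of stored offset i+k is L-1-(i+k), so the
                # block's smallest query position pairs with its largest
                # target position
                q_min = region.region_start + L - 1 - (i + op.length - 1)
                blocks.append(MapBlock(q_min, t + op.length - 1, op.length))
            else:
                blocks.append(MapBlock(region.region_start + i, t, op.length))
            i += op.length
            t += op.length
        elif op.code in "ISH":
            i += op.length
        elif op.code in "DN":
            t += op.length
        # P consumes neither

    cmap = CoordinateMap(
        gene_id=region.gene_id,
        query_chrom=region.chrom,
        target_chrom=rec.rname or "",
        orientation=REVERSE if reverse else FORWARD,
        blocks=blocks,
    )
    cmap.blocks = _merge_adjacent(cmap.blocks, cmap.orientation)
    cmap._starts = [b.query_start for b in cmap.blocks]
    return cmap


def _merge_adjacent(blocks: list[MapBlock], orientation: str) -> list[MapBlock]:
    """Merge blocks contiguous on both genomes (already query-sorted)."""
    merged: list[MapBlock] = []
    for b in blocks:
        if merged:
            a = merged[-1]
            contiguous_q = b.query_start == a.query_start + a.length
            if orientation == FORWARD:
                contiguous_t = b.target_start == a.target_start + a.length
                if contiguous_q and contiguous_t:
                    merged[-1] = MapBlock(a.query_start, a.target_start, a.length + b.length)
                    continue
            else:
                # a covers targets [a.target_start-a.length+1, a.target_start];
                # b must sit directly below it
                contiguous_t = b.target_start == a.target_start - a.length
                if contiguous_q and contiguous_t:
                    merged[-1] = MapBlock(a.query_start, a.target_start, a.length + b.length)
                    continue
        merged.append(b)
    return merged


class MapIndex:
    """Per-query-chromosome interval lookup over coordinate-map spans."""

    def __init__(self, maps: list[CoordinateMap]):
        self.maps = maps
        self._trees: dict[str, IntervalTree] = {}
        for cmap in maps:
            start, end = cmap.query_span
            if start >= end:
                continue
            self._trees.setdefault(cmap.query_chrom, IntervalTree()).addi(
                start, end, cmap
            )

    def query(self, chrom: str, pos: int) -> list[CoordinateMap]:
        """Maps whose query span contains *pos* (gene-id order)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        return sorted(hits, key=lambda m: m.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[CoordinateMap]:
        """Maps whose query span overlaps [start, end) (gene-id order)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda m: m.gene_id)


def build_index(maps: list[CoordinateMap]) -> MapIndex:
    return MapIndex(maps)


def lift_position(
    index: MapIndex, chrom: str, pos: int
) -> list[tuple[str, str, int, str]]:
    """Lift one query position through every covering map.

    Returns ``(gene_id, target_chrom, target_pos, orientation)`` tuples in
    gene-id order; a position in no map, or in an inter-block gap, yields
    nothing.
    """
    out = []
    for cmap in index.query(chrom, pos):
        t = cmap.lift(pos)
        if t is not None:
            out.append((cmap.gene_id, cmap.target_chrom, t, cmap.orientation))
    return out


# ---------------------------------------------------------------------------
# Persistence: one block per line, tab-separated


def save_maps(maps: list[CoordinateMap], path) -> None:
    with open(path, "w") as fh:
        for cmap in maps:
            for b in cmap.blocks:
                fh.write(
                    "\t".join(
                        (
                            cmap.gene_id,
                            cmap.query_chrom,
                            str(b.query_start),
                            cmap.target_chrom,
                            str(b.target_start),
                            str(b.length),
                            cmap.orientation,
                        )
                    )
                    + "\n"
                )


def load_maps(path) -> list[CoordinateMap]:
    """Inverse of :func:`save_maps`; blocks regroup by gene id in file order."""
    maps: dict[str, CoordinateMap] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            gene, qchrom, qstart, tchrom, tstart, length, orientation = cols
            if orientation not in (FORWARD, REVERSE):
                raise FormatError(f"{path}:{lineno}: bad orientation {orientation!r}")
            try:
                block = MapBlock(int(qstart), int(tstart), int(length))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate")
            if gene not in maps:
                maps[gene] = CoordinateMap(gene, qchrom, tchrom, orientation, [])
                order.append(gene)
            cmap = maps[gene]
            if (cmap.query_chrom, cmap.target_chrom, cmap.orientation) != (
                qchrom,
                tchrom,
                orientation,
            ):
                raise FormatError(f"{path}:{lineno}: inconsistent map fields for {gene}")
            cmap.blocks.append(block)
    out = []
    for gene in order:
        cmap = maps[gene]
        cmap.blocks.sort(key=lambda b: b.query_start)
        cmap._starts = [b.query_start for b in cmap.blocks]
        out.append(cmap)
    return out
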