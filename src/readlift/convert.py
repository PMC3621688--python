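"""Transform reads from query-genome to target-genome coordinates.

Each mapped read is matched to the coordinate map that explains the most of
its aligned bases, its CIGAR is composed with that map's block structure,
and a new SAM record in target coordinates is emitted.  Reads that land on
non-corresponding positions — outside every gene-region map, or with fewer
lifted bases than ``min_mapped_bases`` — are marked unmapped.  When the
gene region aligned to the opposite target strand, the read's strand bit is
toggled and SEQ/QUAL reversed so the output is valid target-forward SAM.

Composition semantics, per read base (in output/target orientation):

* aligned to a query position that lifts        → M at the lifted position
* aligned to a query position inside the map span that does not lift
  (query-lineage insertion)                     → I
* aligned outside the map span, or already S    → soft clip at the ends
* the read's own insertions                     → I
* jumps between consecutive lifted target positions (the map's deletions,
  or the read's own deletions over lifted positions) → D of the jump size

Insertions left adjacent to the alignment ends after composition are
soft-clipped instead, keeping the CIGAR valid.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .coordmap import FORWARD, REVERSE, CoordinateMap, MapIndex, build_coord_map, build_index, load_maps
from .formats import (
    CigarOp,
    SamRecord,
    Settings,
    canonical_cigar,
    read_fasta,
    read_relations,
    read_sam,
    reverse_complement,
    write_sam,
)
from .homology import resolve, scored_alignments
from .regions import parse_region_header

log = logging.getLogger(__name__)

__all__ = [
    "ConversionStats",
    "UnliftableError",
    "choose_map",
    "compose_cigar",
    "transform_read",
    "transform_file",
    "compute_maps",
]


class UnliftableError(Exception):
    """No read base lifts to a target position under the chosen map."""


@dataclass
class ConversionStats:
    n_input: int = 0
    n_transformed: int = 0
    n_unmapped_out: int = 0
    n_passthrough_unmapped: int = 0
    per_gene: dict[str, int] = field(default_factory=dict)

    def add(self, other: "ConversionStats") -> None:
        self.n_input += other.n_input
        self.n_transformed += other.n_transformed
        self.n_unmapped_out += other.n_unmapped_out
        self.n_passthrough_unmapped += other.n_passthrough_unmapped
        for gene, n in other.per_gene.items():
            self.per_gene[gene] = self.per_gene.get(gene, 0) + n


def _aligned_query_positions(read: SamRecord) -> list[int]:
    """Query positions of the read's M/=/X bases, ascending."""
    out = []
    q = read.pos
    for op in read.cigar or []:
        if op.code in "M=X":
            out.extend(range(q, q + op.length))
            q += op.length
        elif op.code in "DN":
            q += op.length
    return out


def choose_map(
    read: SamRecord, index: MapIndex, min_mapped_bases: int = 1
) -> Optional[CoordinateMap]:
    """Pick the map lifting the most of the read's aligned bases.

    Ties break toward the lexicographically smallest gene id; returns None
    when the best map lifts fewer than *min_mapped_bases* bases.
    """
    positions = _aligned_query_positions(read)
    if not positions:
        return None
    candidates = index.overlapping(read.rname, read.pos, read.pos + read.ref_consumed())
    best: Optional[CoordinateMap] = None
    best_count = 0
    for cmap in candidates:  # already gene-id sorted, so first max wins ties
        count = sum(1 for q in positions if cmap.lift(q) is not None)
        if count > best_count:
            best, best_count = cmap, count
    if best_count < min_mapped_bases:
        return None
    return best


# per-base event kinds used during composition
_CLIP, _INS, _MATCH = "S", "I", "M"


def _base_events(read: SamRecord) -> tuple[list[tuple[str, Optional[int]]], int, int]:
    """Per stored read base: (kind, query position or None); plus H lengths."""
    events: list[tuple[str, Optional[int]]] = []
    lead_h = trail_h = 0
    q = read.pos
    for i, op in enumerate(read.cigar or []):
        if op.code in "M=X":
            events.extend((_MATCH, q + k) for k in range(op.length))
            q += op.length
        elif op.code == "I":
            events.extend([(_INS, None)] * op.length)
        elif op.code == "S":
            events.extend([(_CLIP, None)] * op.length)
        elif op.code in "DN":
            q += op.length
        elif op.code == "H":
            if i == 0:
                lead_h = op.length
            else:
                trail_h = op.length
    return events, lead_h, trail_h


def compose_cigar(
    read: SamRecord, cmap: CoordinateMap
) -> tuple[int, list[CigarOp], int, int]:
    """Compose the read's alignment with *cmap*.

    Returns ``(target_pos, new_cigar, clipped_prefix, clipped_suffix)``:
    the smallest target position of any M base, the canonical CIGAR in
    target-forward orientation, and the number of read bases newly
    soft-clipped at each end (counted in the read's stored orientation,
    pre-existing soft clips excluded).  Raises :class:`UnliftableError`
    when no base lifts.
    """
    span_start, span_end = cmap.query_span
    events, lead_h, trail_h = _base_events(read)

    composed: list[tuple[str, Optional[int], bool]] = []  # (kind, target, newly_clipped)
    for kind, q in events:
        if kind == _MATCH:
            if q < span_start or q >= span_end:
                composed.append((_CLIP, None, True))
            else:
                t = cmap.lift(q)
                if t is None:
                    composed.append((_INS, None, False))
                else:
                    composed.append((_MATCH, t, False))
        else:
            composed.append((kind, None, False))

    m_idx = [i for i, (kind, _, _) in enumerate(composed) if kind == _MATCH]
    if not m_idx:
        raise UnliftableError(read.qname)
    first, last = m_idx[0], m_idx[-1]
    clipped_prefix = sum(
        1 for kind, _, new in composed[:first] if new or kind == _INS
    )
    clipped_suffix = sum(
        1 for kind, _, new in composed[last + 1 :] if new or kind == _INS
    )

    if cmap.orientation == REVERSE:
        composed.reverse()
        first, last = len(composed) - 1 - last, len(composed) - 1 - first
        lead_h, trail_h = trail_h, lead_h

    ops: list[CigarOp] = []
    if lead_h:
        ops.append(CigarOp("H", lead_h))
    if first:
        ops.append(CigarOp("S", first))
    target_pos = None
    prev_t = None
    for kind, t, _ in composed[first : last + 1]:
        if kind == _MATCH:
            if target_pos is None:
                target_pos = t
            elif t - prev_t - 1 > 0:
                ops.append(CigarOp("D", t - prev_t - 1))
            ops.append(CigarOp("M", 1))
            prev_t = t
        else:  # _INS (interior; interior S cannot occur)
            ops.append(CigarOp("I", 1))
    n_suffix = len(composed) - 1 - last
    if n_suffix:
        ops.append(CigarOp("S", n_suffix))
    if trail_h:
        ops.append(CigarOp("H", trail_h))
    return target_pos, canonical_cigar(ops), clipped_prefix, clipped_suffix


def _unmap(read: SamRecord) -> SamRecord:
    """Mark a read unmapped (non-corresponding position)."""
    seq, qual = read.seq, read.qual
    if read.is_reverse and seq != "*":
        seq = reverse_complement(seq)
        qual = qual[::-1] if qual != "*" else qual
    flag = (read.flag | 0x4) & ~0x10 & ~0x2
    return read.with_(
        flag=flag,
        rname=None,
        pos=-1,
        mapq=0,
        cigar=None,
        rnext=None,
        pnext=-1,
        tlen=0,
        seq=seq,
        qual=qual,
        tags=_strip_tags(read.tags),
    )


def _strip_tags(tags):
    return tuple(t for t in tags if t[0] not in ("MD", "NM"))


def _transform(
    read: SamRecord, index: MapIndex, min_mapped_bases: int
) -> tuple[SamRecord, str, Optional[str]]:
    if not read.is_mapped:
        return (
            read.with_(rname=None, pos=-1, rnext=None, pnext=-1, tlen=0),
            "passthrough",
            None,
        )
    cmap = choose_map(read, index, min_mapped_bases)
    if cmap is None:
        return _unmap(read), "unmapped", None
    try:
        target_pos, cigar, _, _ = compose_cigar(read, cmap)
    except UnliftableError:
        return _unmap(read), "unmapped", None
    flag = read.flag & ~0x2
    seq, qual = read.seq, read.qual
    if cmap.orientation == REVERSE:
        flag ^= 0x10
        if seq != "*":
            seq = reverse_complement(seq)
        if qual != "*":
            qual = qual[::-1]
    out = read.with_(
        flag=flag,
        rname=cmap.target_chrom,
        pos=target_pos,
        cigar=cigar,
        rnext=None,
        pnext=-1,
        tlen=0,
        seq=seq,
        qual=qual,
        tags=_strip_tags(read.tags),
    )
    return out, "transformed", cmap.gene_id


def transform_read(read: SamRecord, index: MapIndex, min_mapped_bases: int = 1) -> SamRecord:
    """Transform one read to target coordinates (see module docstring)."""
    return _transform(read, index, min_mapped_bases)[0]


def compute_maps(settings: Settings) -> list[CoordinateMap]:
    """Resolve the gene-alignment SAM and build all coordinate maps.

    The region each alignment refers to is recovered from its QNAME (the
    extraction stage's header grammar), so only the alignment SAM and the
    optional relation table are consulted.
    """
    _, alns = read_sam(settings.gene_alignment_sam)
    prefs = (
        read_relations(settings.relation_file) if settings.relation_file else []
    )
    resolved = resolve(
        scored_alignments(alns), prefs, settings.reciprocal_filter
    )
    return [
        build_coord_map(aln, parse_region_header(aln.record.qname))
        for aln in resolved
    ]


def _transform_chunk(args) -> tuple[list[SamRecord], ConversionStats]:
    records, maps, min_mapped_bases = args
    index = build_index(maps)
    out = []
    stats = ConversionStats()
    for read in records:
        rec, kind, gene = _transform(read, index, min_mapped_bases)
        out.append(rec)
        stats.n_input += 1
        if kind == "transformed":
            stats.n_transformed += 1
            stats.per_gene[gene] = stats.per_gene.get(gene, 0) + 1
        elif kind == "unmapped":
            stats.n_unmapped_out += 1
        else:
            stats.n_passthrough_unmapped += 1
    return out, stats


def transform_file(
    settings: Settings, maps: Optional[list[CoordinateMap]] = None
) -> ConversionStats:
    """Run the conversion stage end to end, writing ``settings.output_sam``.

    Maps come from, in order of preference: the *maps* argument, the
    ``maps_file`` named in the settings, or an in-process resolve+combine
    over the gene-alignment SAM.  With ``n_jobs > 1`` the input is split
    into contiguous chunks processed independently and concatenated in
    order, so the output is byte-identical to a serial run.
    """
    if maps is None:
        if settings.maps_file is not None and settings.maps_file.exists():
            maps = load_maps(settings.maps_file)
        else:
            maps = compute_maps(settings)
    target = read_fasta(settings.target_genome)
    header = ["@HD\tVN:1.6\tSO:unknown"]
    header.extend(f"@SQ\tSN:{rec.id}\tLN:{len(rec)}" for rec in target)
    header.append(f"@PG\tID:readlift\tPN:readlift\tVN:{__version__}")

    _, reads = read_sam(settings.reads_sam)
    n_jobs = settings.n_jobs
    if n_jobs > 1 and len(reads) > 1:
        size = (len(reads) + n_jobs - 1) // n_jobs
        chunks = [
            (reads[i : i + size], maps, settings.min_mapped_bases)
            for i in range(0, len(reads), size)
        ]
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(_transform_chunk, chunks))
    else:
        results = [_transform_chunk((reads, maps, settings.min_mapped_bases))]

    stats = ConversionStats()
    out_records: list[SamRecord] = []
    for recs, chunk_stats in results:
        out_records.extend(recs)
        stats.add(chunk_stats)
    write_sam(settings.output_sam, header, out_records)
    log.info(
        "converted %d reads: %d transformed, %d newly unmapped, %d passthrough",
        stats.n_input,
        stats.n_transformed,
        stats.n_unmapped_out,
        stats.n_passthrough_unmapped,
    )
    return stats
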