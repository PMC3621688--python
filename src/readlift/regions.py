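"""Strand-aware flanked gene regions and their FASTA extraction.

Each annotated gene is extended by an upstream flank on its 5' side (left of
the gene on "+", right on "−") and a downstream flank on its 3' side, then
truncated at the chromosome boundaries.  The extracted sequence is ALWAYS
the forward genomic strand — never reverse-complemented — so the downstream
alignment step carries the only orientation flag in the pipeline; the gene
strand is recorded in the FASTA header purely as provenance.

The header grammar ``<gene_id>::<chrom>:<start>-<end>(<strand>)`` (0-based
half-open coordinates) is the contract that lets later stages recover the
region a gene-to-target alignment refers to from its SAM QNAME alone.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .formats import FormatError, GffFeature, SequenceRecord

log = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "compute_region",
    "compute_regions",
    "extract_sequences",
    "format_region_id",
    "parse_region_header",
]


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval plus its flank-extended region, 0-based half-open."""

    gene_id: str
    chrom: str
    gene_start: int
    gene_end: int
    strand: str  # "+" or "-"
    region_start: int
    region_end: int

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start


def compute_region(
    feature: GffFeature,
    flank_upstream: int,
    flank_downstream: int,
    chrom_length: int,
) -> GeneRegion:
    """Extend *feature* by strand-aware flanks, clamped to the chromosome.

    The upstream flank sits 5' of the transcription start site and the
    downstream flank 3' of the gene end; both are silently truncated at the
    chromosome boundaries.  An unstranded feature (".") is treated as "+"
    with a warning.
    """
    strand = feature.strand
    if strand == ".":
        log.warning(
            "feature %s has no strand; treating as '+'",
            feature.attributes.get("ID", "?"),
        )
        strand = "+"
    if feature.end <= 0 or feature.start >= chrom_length:
        raise FormatError(
            f"feature {feature.attributes.get('ID', '?')} "
            f"[{feature.start},{feature.end}) lies outside chromosome "
            f"{feature.seqid} (length {chrom_length})"
        )
    if strand == "+":
        left, right = flank_upstream, flank_downstream
    else:
        left, right = flank_downstream, flank_upstream
    return GeneRegion(
        gene_id=feature.id,
        chrom=feature.seqid,
        gene_start=feature.start,
        gene_end=feature.end,
        strand=strand,
        region_start=max(0, feature.start - left),
        region_end=min(chrom_length, feature.end + right),
    )


def compute_regions(
    features: list[GffFeature],
    chrom_lengths: dict[str, int],
    flank_upstream: int,
    flank_downstream: int,
) -> list[GeneRegion]:
    """Vector form of :func:`compute_region` over an annotation."""
    regions = []
    for feat in features:
        if feat.seqid not in chrom_lengths:
            raise FormatError(f"unknown chromosome {feat.seqid!r} in annotation")
        regions.append(
            compute_region(
                feat, flank_upstream, flank_downstream, chrom_lengths[feat.seqid]
            )
        )
    return regions


def format_region_id(region: GeneRegion) -> str:
    return (
        f"{region.gene_id}::{region.chrom}:"
        f"{region.region_start}-{region.region_end}({region.strand})"
    )


_HEADER_RE = re.compile(
    r"^(?P<gene>.+)::(?P<chrom>.+):(?P<start>\d+)-(?P<end>\d+)"
    r"\((?P<strand>[+-])\)$"
)


def parse_region_header(header_id: str) -> GeneRegion:
    """Invert :func:`format_region_id`.

    The flank-free gene bounds are not encoded in the header, so they are
    set equal to the region bounds.
    """
    m = _HEADER_RE.match(header_id)
    if m is None:
        raise FormatError(f"malformed region header {header_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if start >= end:
        raise FormatError(f"empty region in header {header_id!r}")
    return GeneRegion(
        gene_id=m["gene"],
        chrom=m["chrom"],
        gene_start=start,
        gene_end=end,
        strand=m["strand"],
        region_start=start,
        region_end=end,
    )


def extract_sequences(
    genome: list[SequenceRecord], regions: list[GeneRegion]
) -> list[SequenceRecord]:
    """Cut each region's forward-strand sequence out of the genome.

    Output order follows the input region order; each record's id is the
    region header (see :func:`format_region_id`).
    """
    by_id = {rec.id: rec for rec in genome}
    out = []
    for region in regions:
        if region.chrom not in by_id:
            raise FormatError(f"unknown chromosome {region.chrom!r} in genome FASTA")
        chrom = by_id[region.chrom]
        if region.region_end > len(chrom):
            raise FormatError(
                f"region {region.gene_id} ends at {region.region_end} beyond "
                f"chromosome {region.chrom} (length {len(chrom)})"
            )
        rid = format_region_id(region)
        out.append(
            SequenceRecord(
                id=rid,
                description=rid,
                sequence=chrom.sequence[region.region_start : region.region_end],
            )
        )
    return out
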