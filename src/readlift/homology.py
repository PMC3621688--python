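"""Reduce gene-to-target alignments to at most one alignment per gene.

Paralogous genes make gene-region-to-genome alignments one-to-many or
many-to-many.  Selection happens in two tiers: user-asserted gene→target
relations first, then the alignment score (``AS`` tag, falling back to the
count of aligned read bases).  An optional reciprocal-overlap filter
additionally removes surviving alignments whose target footprints largely
coincide, keeping only the best-scoring occupant of each target locus.

All choices are made under a total order (score, target sequence name,
target start, input position), so the result is independent of input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .formats import RelationPreference, SamRecord
from .regions import parse_region_header

log = logging.getLogger(__name__)

__all__ = [
    "ScoredAlignment",
    "alignment_score",
    "matches_preference",
    "resolve",
    "scored_alignments",
]

# fraction of the shorter target span two alignments must share before the
# reciprocal filter treats them as competing for the same locus
RECIPROCAL_OVERLAP_FRACTION = 0.5


def alignment_score(record: SamRecord) -> float:
    """Alignment score: the ``AS:i`` tag, else the aligned-base count.

    The fallback sums the query-consuming, reference-aligned CIGAR lengths
    (M/=/X), which keeps SAM converted from aligners that emit no ``AS``
    usable.
    """
    tag = record.get_tag("AS")
    if tag is not None:
        return float(tag[1])
    return float(
        sum(op.length for op in record.cigar or [] if op.code in "M=X")
    )


@dataclass(frozen=True)
class ScoredAlignment:
    """A mapped gene-region alignment with its selection key material."""

    record: SamRecord
    gene_id: str
    target_seq: str
    target_span: tuple[int, int]  # 0-based half-open on the target
    score: float
    index: int  # position in the input, the final tie-break

    @classmethod
    def from_record(cls, record: SamRecord, index: int = 0) -> "ScoredAlignment":
        region = parse_region_header(record.qname)
        start = record.pos
        return cls(
            record=record,
            gene_id=region.gene_id,
            target_seq=record.rname or "",
            target_span=(start, start + record.ref_consumed()),
            score=alignment_score(record),
            index=index,
        )


def scored_alignments(records: list[SamRecord]) -> list[ScoredAlignment]:
    """Wrap mapped primary records; unmapped/secondary/supplementary drop."""
    out = []
    for i, rec in enumerate(records):
        if not rec.is_mapped or rec.is_secondary or rec.is_supplementary:
            continue
        out.append(ScoredAlignment.from_record(rec, index=i))
    return out


def matches_preference(aln: ScoredAlignment, pref: RelationPreference) -> bool:
    """True iff *aln* lands on the preferred sequence (and interval)."""
    if aln.target_seq != pref.target_seq:
        return False
    if pref.target_interval is None:
        return True
    ps, pe = pref.target_interval
    s, e = aln.target_span
    return max(s, ps) < min(e, pe)


def _selection_key(aln: ScoredAlignment) -> tuple:
    # best-first total order: high score, then lexicographic target name,
    # then leftmost target start, then first occurrence
    return (-aln.score, aln.target_seq, aln.target_span[0], aln.index)


def resolve(
    alignments: list[ScoredAlignment],
    preferences: list[RelationPreference],
    reciprocal_overlap_filter: bool = False,
) -> list[ScoredAlignment]:
    """Select at most one alignment per gene.

    Per gene: candidates failing every stated preference for that gene are
    discarded (genes with no stated preference keep all candidates), then
    the best candidate under the total order survives.  With
    *reciprocal_overlap_filter*, survivors whose target spans overlap
    another survivor's by more than half of the shorter span are dropped in
    favour of the better-scoring one.  Output is sorted by gene id.
    """
    prefs_by_gene: dict[str, list[RelationPreference]] = {}
    for pref in preferences:
        prefs_by_gene.setdefault(pref.query_gene_id, []).append(pref)

    by_gene: dict[str, list[ScoredAlignment]] = {}
    for aln in alignments:
        if not aln.record.is_mapped or aln.record.is_secondary or aln.record.is_supplementary:
            continue
        by_gene.setdefault(aln.gene_id, []).append(aln)

    for gene in prefs_by_gene:
        if gene not in by_gene:
            log.warning("relation preference for gene %s matches no alignment", gene)

    winners: list[ScoredAlignment] = []
    for gene, candidates in by_gene.items():
        prefs = prefs_by_gene.get(gene)
        if prefs:
            candidates = [
                a for a in candidates if any(matches_preference(a, p) for p in prefs)
            ]
        if not candidates:
            continue
        winners.append(min(candidates, key=_selection_key))

    if reciprocal_overlap_filter:
        accepted: list[ScoredAlignment] = []
        for aln in sorted(winners, key=_selection_key):
            if not any(_competing(aln, other) for other in accepted):
                accepted.append(aln)
        winners = accepted

    return sorted(winners, key=lambda a: a.gene_id)


def _competing(a: ScoredAlignment, b: ScoredAlignment) -> bool:
    if a.target_seq != b.target_seq:
        return False
    (s1, e1), (s2, e2) = a.target_span, b.target_span
    overlap = min(e1, e2) - max(s1, s2)
    shorter = min(e1 - s1, e2 - s2)
    return shorter > 0 and overlap > RECIPROCAL_OVERLAP_FRACTION * shorter
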