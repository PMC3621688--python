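"""Readers and writers for the text formats the pipeline touches.

FASTA, GFF3, SAM, the INI configuration and the gene-relation table are
parsed here and nowhere else.  All coordinates are exposed to the rest of
the package as 0-based half-open intervals; the 1-based conventions of GFF3
(inclusive) and SAM (``POS``) are converted at the parse/serialize boundary
in this module only, so no other module ever performs ``+/-1`` arithmetic on
file coordinates.

SAM records are kept deliberately close to the on-disk representation:
optional tags travel as opaque ``(tag, type, value-string)`` triples so that
``write_sam(read_sam(x))`` reproduces mandatory fields and tags
byte-for-byte for valid input.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import gffutils.feature
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GffFeature",
    "CigarOp",
    "SamRecord",
    "Settings",
    "RelationPreference",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "read_sam",
    "write_sam",
    "read_settings",
    "read_relations",
    "reverse_complement",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA sequence: identifier, free-text description, uppercase DNA."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, file order.

    Multi-line sequences are concatenated and lowercase bases uppercased.
    An empty file or a duplicate identifier is an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, rec.description, str(rec.seq).upper())
        )
    if not records:
        raise FormatError(f"no sequences in {path}")
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 feature row with 0-based half-open coordinates.

    ``attributes`` maps keys to their (first) percent-decoded value; gene
    features must carry an ``ID``.
    """

    seqid: str
    type: str
    start: int  # 0-based inclusive
    end: int  # half-open
    strand: str  # one of "+", "-", "."
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.attributes["ID"]


def read_gff3_genes(path, feature_type: str = "gene") -> list[GffFeature]:
    """Read the rows of one feature type from a GFF3 file, order preserved.

    Comment/directive lines are skipped.  A selected row lacking an ``ID``
    attribute, or with start > end, is an error citing the line number.
    """
    features: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions
                raise FormatError(f"{path}:{lineno}: malformed GFF3 row: {exc}")
            if feat.featuretype != feature_type:
                continue
            if feat.start > feat.end:
                raise FormatError(
                    f"{path}:{lineno}: start {feat.start} > end {feat.end}"
                )
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            if "ID" not in attrs:
                raise FormatError(
                    f"{path}:{lineno}: {feature_type} row lacks an ID attribute"
                )
            features.append(
                GffFeature(
                    seqid=feat.seqid,
                    type=feat.featuretype,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    attributes=attrs,
                )
            )
    return features


# ---------------------------------------------------------------------------
# SAM

# CIGAR codes consuming read bases / reference bases.
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")
CIGAR_CODES = frozenset("MIDNSHP=X")

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class CigarOp:
    code: str
    length: int

    def __str__(self) -> str:
        return f"{self.length}{self.code}"


def parse_cigar(text: str) -> Optional[list[CigarOp]]:
    if text == "*":
        return None
    ops: list[CigarOp] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in CIGAR_CODES and num:
            ops.append(CigarOp(ch, int(num)))
            num = ""
        else:
            raise FormatError(f"malformed CIGAR {text!r}")
    if num or not ops:
        raise FormatError(f"malformed CIGAR {text!r}")
    return ops


def cigar_to_str(ops: Optional[list[CigarOp]]) -> str:
    if ops is None:
        return "*"
    return "".join(str(op) for op in ops)


def canonical_cigar(ops: Iterable[CigarOp]) -> list[CigarOp]:
    """Merge adjacent same-code operations and drop zero-length ones."""
    out: list[CigarOp] = []
    for op in ops:
        if op.length == 0:
            continue
        if out and out[-1].code == op.code:
            out[-1] = CigarOp(op.code, out[-1].length + op.length)
        else:
            out.append(op)
    return out


@dataclass(frozen=True)
class SamRecord:
    """One SAM alignment line with 0-based coordinates.

    ``pos``/``pnext`` are 0-based (−1 for the file value 0, i.e. unset);
    ``rname``/``rnext`` are ``None`` for ``*``.  Optional tags are opaque
    ``(tag, type, value)`` string triples in file order.
    """

    qname: str
    flag: int
    rname: Optional[str]
    pos: int
    mapq: int
    cigar: Optional[list[CigarOp]]
    rnext: Optional[str]
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: tuple[tuple[str, str, str], ...] = ()

    # -- flag helpers -------------------------------------------------------
    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    # -- CIGAR accounting ---------------------------------------------------
    def query_consumed(self) -> int:
        return sum(op.length for op in self.cigar or [] if op.code in QUERY_CONSUMING)

    def ref_consumed(self) -> int:
        return sum(op.length for op in self.cigar or [] if op.code in REF_CONSUMING)

    def get_tag(self, tag: str) -> Optional[tuple[str, str]]:
        """Return (type, value) for *tag*, or None."""
        for t, typ, val in self.tags:
            if t == tag:
                return typ, val
        return None

    def with_(self, **kw) -> "SamRecord":
        return replace(self, **kw)


def _parse_sam_line(line: str, lineno: int, path) -> SamRecord:
    fields = line.split("\t")
    if len(fields) < 11:
        raise FormatError(f"{path}:{lineno}: SAM record has {len(fields)} fields")
    qname, flag, rname, pos, mapq, cigar, rnext, pnext, tlen, seq, qual = fields[:11]
    tags = []
    for raw in fields[11:]:
        parts = raw.split(":", 2)
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: malformed tag {raw!r}")
        tags.append((parts[0], parts[1], parts[2]))
    rec = SamRecord(
        qname=qname,
        flag=int(flag),
        rname=None if rname == "*" else rname,
        pos=int(pos) - 1,
        mapq=int(mapq),
        cigar=parse_cigar(cigar),
        rnext=None if rnext == "*" else rnext,
        pnext=int(pnext) - 1,
        tlen=int(tlen),
        seq=seq,
        qual=qual,
        tags=tuple(tags),
    )
    if rec.is_mapped and rec.cigar is not None and rec.seq != "*":
        if rec.query_consumed() != len(rec.seq):
            raise FormatError(
                f"{path}:{lineno}: CIGAR/SEQ length mismatch for read {qname!r}: "
                f"CIGAR consumes {rec.query_consumed()} bases, SEQ has {len(rec.seq)}"
            )
    return rec


def read_sam(path) -> tuple[list[str], list[SamRecord]]:
    """Read a text SAM file into (header lines, records).

    Header lines are kept verbatim (without trailing newline).
    """
    header: list[str] = []
    records: list[SamRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                header.append(line)
            else:
                records.append(_parse_sam_line(line, lineno, path))
    return header, records


def sam_record_to_line(rec: SamRecord) -> str:
    fields = [
        rec.qname,
        str(rec.flag),
        rec.rname if rec.rname is not None else "*",
        str(rec.pos + 1),
        str(rec.mapq),
        cigar_to_str(rec.cigar),
        rec.rnext if rec.rnext is not None else "*",
        str(rec.pnext + 1),
        str(rec.tlen),
        rec.seq,
        rec.qual,
    ]
    fields.extend(f"{t}:{typ}:{val}" for t, typ, val in rec.tags)
    return "\t".join(fields)


def write_sam(path, header: Iterable[str], records: Iterable[SamRecord]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for rec in records:
            fh.write(sam_record_to_line(rec) + "\n")


# ---------------------------------------------------------------------------
# Settings (INI)


@dataclass
class Settings:
    """Pipeline configuration, normally read from ``settings.ini``.

    Paths are resolved relative to the INI file's directory.  Flank lengths
    are in bp; the 500 bp defaults match the upstream/downstream extension
    the extraction stage applies around each gene.
    """

    reads_sam: Path
    query_genome: Path
    query_gff3: Path
    target_genome: Path
    gene_alignment_sam: Path
    output_sam: Path
    flank_upstream: int = 500
    flank_downstream: int = 500
    relation_file: Optional[Path] = None
    n_jobs: int = 1
    min_mapped_bases: int = 1
    feature_type: str = "gene"
    maps_file: Optional[Path] = None
    reciprocal_filter: bool = False

    def __post_init__(self) -> None:
        if self.flank_upstream < 0 or self.flank_downstream < 0:
            raise FormatError("flank lengths must be >= 0")
        if self.n_jobs < 1:
            raise FormatError("n_jobs must be >= 1")
        if self.min_mapped_bases < 1:
            raise FormatError("min_mapped_bases must be >= 1")


_REQUIRED_KEYS = (
    "reads_sam",
    "query_genome",
    "query_gff3",
    "target_genome",
    "gene_alignment_sam",
    "output_sam",
)


def read_settings(path) -> Settings:
    """Parse a settings INI file (one ``[readlift]`` section).

    A file whose single section carries another name is accepted too, so
    configs written for earlier pipeline layouts keep working.  Missing
    optional keys take their defaults; a missing required path key is an
    error naming the key.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FormatError(f"cannot read settings file {path}")
    if parser.has_section("readlift"):
        section = parser["readlift"]
    elif len(parser.sections()) == 1:
        section = parser[parser.sections()[0]]
    else:
        raise FormatError(f"{path}: expected one [readlift] section")

    base = Path(path).resolve().parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    kw = {}
    for key in _REQUIRED_KEYS:
        if key not in section:
            raise FormatError(f"{path}: missing required key {key!r}")
        kw[key] = resolve(section[key])
    for key in ("flank_upstream", "flank_downstream", "n_jobs", "min_mapped_bases"):
        if key in section:
            kw[key] = section.getint(key)
    if section.get("relation_file"):
        kw["relation_file"] = resolve(section["relation_file"])
    if section.get("maps_file"):
        kw["maps_file"] = resolve(section["maps_file"])
    if "feature_type" in section:
        kw["feature_type"] = section["feature_type"]
    if "reciprocal_filter" in section:
        kw["reciprocal_filter"] = section.getboolean("reciprocal_filter")
    return Settings(**kw)


# ---------------------------------------------------------------------------
# Relation preference table


@dataclass(frozen=True)
class RelationPreference:
    """A user-asserted allowed target for one query gene.

    ``target_interval`` is 0-based half-open on the target sequence (the
    file dialect is 1-based inclusive ``seq:start-end``).
    """

    query_gene_id: str
    target_seq: str
    target_interval: Optional[tuple[int, int]] = None


def read_relations(path) -> list[RelationPreference]:
    """Read the two-column TSV of gene→target preferences.

    Column 2 is either a sequence name or ``seq:start-end`` (1-based
    inclusive).  Repeated lines for one gene accumulate: a gene may list
    several allowed targets.
    """
    prefs: list[RelationPreference] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene, spec = cols
            if ":" in spec:
                seq, _, ivl = spec.rpartition(":")
                try:
                    s_str, e_str = ivl.split("-")
                    start, end = int(s_str), int(e_str)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: malformed interval {ivl!r}")
                if start > end or start < 1:
                    raise FormatError(
                        f"{path}:{lineno}: invalid interval {start}-{end}"
                    )
                prefs.append(RelationPreference(gene, seq, (start - 1, end)))
            else:
                prefs.append(RelationPreference(gene, spec))
    return prefs
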