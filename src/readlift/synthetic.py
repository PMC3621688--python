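"""Self-contained simulation of a query/target species pair with truth.

The generator produces everything the pipeline consumes — a random query
genome, a mutated sister ("target") genome, gene annotations, error-free
pre-aligned reads, and gene-region-to-target alignments derived from the
exact mutation record — so every stage can be exercised without external
aligners or downloads.

The mutation model applies mutually exclusive per-base events left to
right: substitutions (coordinates preserved), insertions of 1..max_indel_len
random bases after the current base, and deletions of 1..max_indel_len
bases.  The resulting :class:`TruthMap` lists every surviving base's
(query, target) coordinate pair and is the oracle every lifted position is
checked against.  Defaults emulate a closely related species pair in which
gene regions stay alignable end to end: per-base substitution rate 1%, and
0.2% insertion/deletion event rates with lengths up to 10 bp ("short
deletions and several SNPs" territory, not structural divergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .formats import (
    CigarOp,
    FormatError,
    GffFeature,
    SamRecord,
    SequenceRecord,
    canonical_cigar,
    reverse_complement,
    write_fasta,
    write_sam,
)
from .regions import GeneRegion, compute_regions, extract_sequences, format_region_id

__all__ = [
    "MutationModel",
    "TruthMap",
    "random_genome",
    "mutate_genome",
    "plant_genes",
    "truth_alignment_sam",
    "simulate_reads",
    "oracle_lift",
    "generate_dataset",
    "DEFAULTS",
]

# Study-condition defaults for the end-to-end simulated pair.
DEFAULTS = dict(
    chrom_lengths={"chr1": 50_000, "chr2": 50_000},
    n_genes=20,
    gene_length_range=(500, 1500),
    flank_gap=1200,
    snp_rate=0.01,
    ins_rate=0.002,
    del_rate=0.002,
    max_indel_len=10,
    n_reads=5000,
    read_length=75,
    fraction_outside=0.2,
    flank=500,
    seed=42,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationModel:
    """Per-base event probabilities for the sister-genome simulation."""

    snp_rate: float = 0.01
    ins_rate: float = 0.002
    del_rate: float = 0.002
    max_indel_len: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.snp_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.snp_rate + self.ins_rate + self.del_rate > 1:
            raise ValueError("snp_rate + ins_rate + del_rate must be <= 1")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


@dataclass
class TruthMap:
    """Exact per-base query→target correspondence, per chromosome.

    Functional and injective; substituted positions are present (their
    coordinates still correspond), deleted query positions and inserted
    target positions are absent.
    """

    pairs: dict[str, dict[int, int]] = field(default_factory=dict)

    def lift(self, chrom: str, pos: int) -> Optional[int]:
        return self.pairs.get(chrom, {}).get(pos)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.pairs:
                for q, t in sorted(self.pairs[chrom].items()):
                    fh.write(f"{chrom}\t{q}\t{t}\n")

    @classmethod
    def load(cls, path) -> "TruthMap":
        pairs: dict[str, dict[int, int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 columns")
                pairs.setdefault(cols[0], {})[int(cols[1])] = int(cols[2])
        return cls(pairs)


def oracle_lift(truth: TruthMap, chrom: str, pos: int) -> Optional[int]:
    """Direct truth lookup — the independent lifting oracle."""
    return truth.lift(chrom, pos)


def random_genome(chrom_lengths: dict[str, int], seed: int) -> list[SequenceRecord]:
    """Uniform i.i.d. A/C/G/T chromosomes, reproducible per seed."""
    rng = np.random.default_rng(seed)
    records = []
    for name, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {name!r} length must be >= 1")
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        records.append(SequenceRecord(name, name, seq))
    return records


def mutate_genome(
    genome: list[SequenceRecord], model: MutationModel
) -> tuple[list[SequenceRecord], TruthMap]:
    """Apply the mutation model, returning the sister genome and its truth.

    Events are sampled per query base, mutually exclusively, left to right;
    indel lengths are uniform on [1, max_indel_len] and insertion bases
    uniform random.  Chromosome names carry over unchanged.
    """
    rng = np.random.default_rng(model.seed)
    p_del = model.del_rate
    p_ins = model.del_rate + model.ins_rate
    p_snp = p_ins + model.snp_rate
    target_records = []
    truth = TruthMap()
    for rec in genome:
        src = rec.sequence
        out: list[str] = []
        pairs: dict[int, int] = {}
        i = 0
        t = 0
        n = len(src)
        while i < n:
            u = rng.random()
            if u < p_del:
                i += int(rng.integers(1, model.max_indel_len + 1))
                continue
            if u < p_ins:
                out.append(src[i])
                pairs[i] = t
                t += 1
                ins_len = int(rng.integers(1, model.max_indel_len + 1))
                out.append(_BASES[rng.integers(0, 4, size=ins_len)].tobytes().decode())
                t += ins_len
                i += 1
                continue
            if u < p_snp:
                alternatives = "ACGT".replace(src[i], "") or "N"
                out.append(alternatives[int(rng.integers(0, len(alternatives)))])
            else:
                out.append(src[i])
            pairs[i] = t
            t += 1
            i += 1
        target_records.append(SequenceRecord(rec.id, rec.id, "".join(out)))
        truth.pairs[rec.id] = pairs
    return target_records, truth


def plant_genes(
    genome: list[SequenceRecord],
    n_genes: int,
    length_range: tuple[int, int] = (500, 1500),
    flank_gap: int = 1200,
    seed: int = 42,
) -> list[GffFeature]:
    """Place non-overlapping genes with random strands across the genome.

    Consecutive genes (and chromosome ends) are separated by at least
    *flank_gap* bases, so with flanks up to ``flank_gap/2`` the extracted
    regions stay disjoint.  Raises when the genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    features: list[GffFeature] = []
    gi = 0
    for rec in genome:
        cursor = flank_gap
        while gi < n_genes:
            length = int(rng.integers(lo, hi + 1))
            jitter = int(rng.integers(0, flank_gap + 1))
            start = cursor + jitter
            if start + length + flank_gap > len(rec):
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            features.append(
                GffFeature(
                    seqid=rec.id,
                    type="gene",
                    start=start,
                    end=start + length,
                    strand=strand,
                    attributes={"ID": f"g{gi:03d}"},
                )
            )
            cursor = start + length + flank_gap
        if gi == n_genes:
            break
    if gi < n_genes:
        raise ValueError(
            f"cannot place {n_genes} genes of {length_range} bp with gap "
            f"{flank_gap} in this genome"
        )
    return features


def truth_alignment_sam(
    regions: list[GeneRegion], truth: TruthMap, genome: list[SequenceRecord]
) -> list[SamRecord]:
    """Exact gene-region-to-target alignments derived from the truth map.

    Stands in for the external long-sequence aligner: runs of corresponding
    bases become M, query-only runs I (or S at the region ends), and
    target-only runs D.  A region with zero corresponding bases yields no
    record.  Alignments are always forward orientation, matching the
    mutation model (no rearrangements).
    """
    sequences = {rec.id: rec.sequence for rec in genome}
    records: list[SamRecord] = []
    for region in regions:
        ops: list[CigarOp] = []
        target_start: Optional[int] = None
        prev_t: Optional[int] = None
        n_match = 0
        for q in range(region.region_start, region.region_end):
            t = truth.lift(region.chrom, q)
            if t is None:
                ops.append(CigarOp("I", 1))
                continue
            if target_start is None:
                target_start = t
            elif t - prev_t - 1 > 0:
                ops.append(CigarOp("D", t - prev_t - 1))
            ops.append(CigarOp("M", 1))
            n_match += 1
            prev_t = t
        if target_start is None:
            continue
        ops = canonical_cigar(ops)
        # leading/trailing query-only runs are soft clips, not insertions
        if ops and ops[0].code == "I":
            ops[0] = CigarOp("S", ops[0].length)
        if ops and ops[-1].code == "I":
            ops[-1] = CigarOp("S", ops[-1].length)
        seq = sequences[region.chrom][region.region_start : region.region_end]
        records.append(
            SamRecord(
                qname=format_region_id(region),
                flag=0,
                rname=region.chrom,
                pos=target_start,
                mapq=60,
                cigar=ops,
                rnext=None,
                pnext=-1,
                tlen=0,
                seq=seq,
                qual="*",
                tags=(("AS", "i", str(n_match)),),
            )
        )
    return records


def simulate_reads(
    genome: list[SequenceRecord],
    regions: list[GeneRegion],
    read_length: int = 75,
    n_reads: int = 5000,
    seed: int = 42,
    fraction_outside: float = 0.2,
) -> list[SamRecord]:
    """Error-free pre-aligned reads from the query genome.

    Each read is an exact genomic substring with an all-M CIGAR; a
    *fraction_outside* share is drawn wholly outside every extracted region
    (exercising the unmapped path).  Reverse-strand reads are stored
    reverse-complemented with flag 0x10 set, as an aligner would emit them.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GeneRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append(region)
    eligible = [r for r in regions if r.region_length >= read_length]
    if fraction_outside < 1 and not eligible:
        raise ValueError("no region long enough for the requested read length")
    reads: list[SamRecord] = []
    for i in range(n_reads):
        outside = rng.random() < fraction_outside
        if outside:
            for _ in range(1000):
                rec = genome[int(rng.integers(0, len(genome)))]
                start = int(rng.integers(0, len(rec) - read_length + 1))
                end = start + read_length
                if not any(
                    max(start, r.region_start) < min(end, r.region_end)
                    for r in by_chrom.get(rec.id, [])
                ):
                    break
            else:
                raise ValueError("could not place a read outside all regions")
            chrom, pos = rec.id, start
            seq = rec.sequence[start:end]
        else:
            region = eligible[int(rng.integers(0, len(eligible)))]
            pos = region.region_start + int(
                rng.integers(0, region.region_length - read_length + 1)
            )
            chrom = region.chrom
            rec = next(g for g in genome if g.id == chrom)
            seq = rec.sequence[pos : pos + read_length]
        reverse = rng.random() < 0.5
        flag = 0x10 if reverse else 0
        stored = reverse_complement(seq) if reverse else seq
        reads.append(
            SamRecord(
                qname=f"read{i:05d}",
                flag=flag,
                rname=chrom,
                pos=pos,
                mapq=60,
                cigar=[CigarOp("M", read_length)],
                rnext=None,
                pnext=-1,
                tlen=0,
                seq=stored,
                qual="I" * read_length,
                tags=(),
            )
        )
    return reads


def write_gff3(path, features: list[GffFeature], source: str = "readlift_sim") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items())
            fh.write(
                "\t".join(
                    (
                        feat.seqid,
                        source,
                        feat.type,
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


def generate_dataset(out_dir, seed: Optional[int] = None, **overrides):
    """Write a complete simulated dataset plus its settings.ini.

    Files: query.fa, target.fa, genes.gff3, regions.fa, reads.sam,
    genes_vs_target.sam, truth.tsv, settings.ini.  Returns the path of the
    settings file.  Keyword overrides replace entries of :data:`DEFAULTS`.
    """
    params = dict(DEFAULTS)
    params.update(overrides)
    if seed is not None:
        params["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(params["seed"])

    genome = random_genome(params["chrom_lengths"], seed=base_seed)
    model = MutationModel(
        snp_rate=params["snp_rate"],
        ins_rate=params["ins_rate"],
        del_rate=params["del_rate"],
        max_indel_len=params["max_indel_len"],
        seed=base_seed + 1,
    )
    target, truth = mutate_genome(genome, model)
    features = plant_genes(
        genome,
        params["n_genes"],
        params["gene_length_range"],
        params["flank_gap"],
        seed=base_seed + 2,
    )
    chrom_lengths = {rec.id: len(rec) for rec in genome}
    regions = compute_regions(features, chrom_lengths, params["flank"], params["flank"])
    region_fasta = extract_sequences(genome, regions)
    gene_alns = truth_alignment_sam(regions, truth, genome)
    reads = simulate_reads(
        genome,
        regions,
        read_length=params["read_length"],
        n_reads=params["n_reads"],
        seed=base_seed + 3,
        fraction_outside=params["fraction_outside"],
    )

    write_fasta(out / "query.fa", genome)
    write_fasta(out / "target.fa", target)
    write_gff3(out / "genes.gff3", features)
    write_fasta(out / "regions.fa", region_fasta)
    truth.save(out / "truth.tsv")

    query_sq = [f"@SQ\tSN:{rec.id}\tLN:{len(rec)}" for rec in genome]
    target_sq = [f"@SQ\tSN:{rec.id}\tLN:{len(rec)}" for rec in target]
    write_sam(out / "reads.sam", ["@HD\tVN:1.6\tSO:unknown"] + query_sq, reads)
    write_sam(
        out / "genes_vs_target.sam",
        ["@HD\tVN:1.6\tSO:unknown"] + target_sq,
        gene_alns,
    )

    ini = out / "settings.ini"
    ini.write_text(
        "[readlift]\n"
        "reads_sam = reads.sam\n"
        "query_genome = query.fa\n"
        "query_gff3 = genes.gff3\n"
        "target_genome = target.fa\n"
        "gene_alignment_sam = genes_vs_target.sam\n"
        "output_sam = converted.sam\n"
        f"flank_upstream = {params['flank']}\n"
        f"flank_downstream = {params['flank']}\n"
    )
    return ini
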