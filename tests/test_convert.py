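"""Read transformation: map choice, CIGAR composition, file conversion."""

import copy
import random

import pytest

from _oracle import composed_read_pairs, invert_map, output_target_positions
from readlift.convert import (
    UnliftableError,
    choose_map,
    compose_cigar,
    transform_file,
    transform_read,
)
from readlift.coordmap import CoordinateMap, MapBlock, build_index
from readlift.formats import (
    CigarOp,
    SamRecord,
    cigar_to_str,
    parse_cigar,
    read_sam,
    reverse_complement,
)


def fmap(gene="g", blocks=((100, 50, 10),), chrom="chrQ", target="chrT",
         orientation="forward"):
    return CoordinateMap(gene, chrom, target, orientation,
                         [MapBlock(*b) for b in blocks])


def read(pos, cigar, flag=0, chrom="chrQ", qname="r1", tags=()):
    ops = parse_cigar(cigar)
    qlen = sum(op.length for op in ops if op.code in "MIS=X")
    return SamRecord(qname, flag, chrom, pos, 37, ops, None, -1, 0,
                     "ACGT" * (qlen // 4) + "ACGT"[: qlen % 4], "I" * qlen, tags)


class TestChooseMap:
    def test_fully_contained_read(self):
        idx = build_index([fmap()])
        assert choose_map(read(102, "5M"), idx).gene_id == "g"

    def test_argmax_on_lifted_bases(self):
        g1 = fmap("g1", blocks=((100, 50, 12),))   # covers 10 of the read
        g2 = fmap("g2", blocks=((90, 500, 40),))   # covers all 30
        idx = build_index([g1, g2])
        assert choose_map(read(102, "30M"), idx).gene_id == "g2"

    def test_tie_breaks_to_smallest_gene_id(self):
        g1 = fmap("g1", blocks=((100, 50, 20),))
        g2 = fmap("g2", blocks=((100, 500, 20),))
        idx = build_index([g2, g1])
        assert choose_map(read(102, "10M"), idx).gene_id == "g1"

    def test_no_coverage_returns_none(self):
        idx = build_index([fmap()])
        assert choose_map(read(500, "10M"), idx) is None

    def test_min_mapped_bases_threshold(self):
        idx = build_index([fmap()])
        r = read(95, "10M")  # only 5 bases inside the map
        assert choose_map(r, idx, min_mapped_bases=5) is not None
        assert choose_map(r, idx, min_mapped_bases=6) is None


class TestComposeCigar:
    def test_identity_composition(self):
        pos, cigar, p, s = compose_cigar(read(100, "10M"), fmap())
        assert (pos, cigar_to_str(cigar), p, s) == (50, "10M", 0, 0)

    def test_map_deletion_appears_in_read(self):
        cmap = fmap(blocks=((100, 50, 4), (104, 56, 6)))
        pos, cigar, p, s = compose_cigar(read(100, "10M"), cmap)
        assert (pos, cigar_to_str(cigar), p, s) == (50, "4M2D6M", 0, 0)

    def test_read_overhang_soft_clipped(self):
        pos, cigar, p, s = compose_cigar(read(96, "10M"), fmap())
        assert (pos, cigar_to_str(cigar), p, s) == (50, "4S6M", 4, 0)

    def test_read_overhang_with_split_map(self):
        # per-base walk: 4 bases precede the span, 4 hit block one, the last
        # 2 hit block two across the 2-base target jump
        cmap = fmap(blocks=((100, 50, 4), (104, 56, 6)))
        pos, cigar, p, s = compose_cigar(read(96, "10M"), cmap)
        assert (pos, cigar_to_str(cigar), p, s) == (50, "4S4M2D2M", 4, 0)

    def test_map_gap_becomes_insertion(self):
        cmap = fmap(blocks=((100, 50, 4), (106, 54, 4)))  # query gap 104-105
        pos, cigar, _, _ = compose_cigar(read(100, "10M"), cmap)
        assert (pos, cigar_to_str(cigar)) == (50, "4M2I4M")

    def test_read_insertion_preserved(self):
        pos, cigar, _, _ = compose_cigar(read(100, "4M2I4M"), fmap())
        assert (pos, cigar_to_str(cigar)) == (50, "4M2I4M")

    def test_read_deletion_over_lifted_positions(self):
        pos, cigar, _, _ = compose_cigar(read(100, "4M2D4M"), fmap())
        assert (pos, cigar_to_str(cigar)) == (50, "4M2D4M")

    def test_read_deletion_over_unlifted_positions_omitted(self):
        cmap = fmap(blocks=((100, 50, 4), (106, 54, 4)))
        pos, cigar, _, _ = compose_cigar(read(100, "4M2D4M"), cmap)
        assert (pos, cigar_to_str(cigar)) == (50, "8M")

    def test_existing_soft_clips_preserved(self):
        pos, cigar, p, s = compose_cigar(read(102, "2S6M"), fmap())
        assert (pos, cigar_to_str(cigar), p, s) == (52, "2S6M", 0, 0)

    def test_reverse_map_reverses_cigar(self):
        cmap = fmap(blocks=((100, 59, 10),), orientation="reverse")
        pos, cigar, _, _ = compose_cigar(read(100, "10M"), cmap)
        assert (pos, cigar_to_str(cigar)) == (50, "10M")
        # asymmetric case: clip ends up on the other side after reversal,
        # and the leftmost lifted target is 54 (q=105 pairs with t=54)
        pos, cigar, _, _ = compose_cigar(read(96, "10M"), cmap)
        assert (pos, cigar_to_str(cigar)) == (54, "6M4S")

    def test_unliftable_raises(self):
        with pytest.raises(UnliftableError):
            compose_cigar(read(100, "10M"), fmap(blocks=((500, 50, 10),)))


class TestTransformRead:
    def test_unmapped_passthrough_clears_refs(self):
        r = SamRecord("u", 4, "chrQ", 9, 0, None, None, -1, 0, "ACGT", "IIII", ())
        out = transform_read(r, build_index([fmap()]))
        assert not out.is_mapped and out.rname is None and out.pos == -1
        assert out.qname == "u" and out.seq == "ACGT"

    def test_non_corresponding_read_marked_unmapped(self):
        out = transform_read(read(500, "10M", tags=(("NM", "i", "0"),)),
                             build_index([fmap()]))
        assert out.flag & 0x4
        assert out.rname is None and out.pos == -1 and out.cigar is None
        assert out.mapq == 0 and not out.is_reverse
        assert out.get_tag("NM") is None

    def test_unmapping_reverse_read_restores_original_sequence(self):
        r = read(500, "10M", flag=0x10)
        out = transform_read(r, build_index([fmap()]))
        assert not out.is_reverse
        assert out.seq == reverse_complement(r.seq)
        assert out.qual == r.qual[::-1]

    def test_forward_lift_preserves_seq_and_mapq(self):
        r = read(102, "5M", tags=(("MD", "Z", "5"), ("XS", "A", "+")))
        out = transform_read(r, build_index([fmap()]))
        assert (out.rname, out.pos, cigar_to_str(out.cigar)) == ("chrT", 52, "5M")
        assert out.seq == r.seq and out.mapq == r.mapq
        assert out.get_tag("MD") is None and out.get_tag("XS") == ("A", "+")

    def test_reverse_map_toggles_strand_and_reverse_complements(self):
        cmap = fmap(blocks=((100, 59, 10),), orientation="reverse")
        r = read(100, "10M")
        out = transform_read(r, build_index([cmap]))
        assert out.is_reverse
        assert out.seq == reverse_complement(r.seq)
        assert out.qual == r.qual[::-1]
        assert (out.rname, out.pos) == ("chrT", 50)

    def test_reverse_read_on_reverse_map_becomes_forward(self):
        cmap = fmap(blocks=((100, 59, 10),), orientation="reverse")
        out = transform_read(read(100, "10M", flag=0x10), build_index([cmap]))
        assert not out.is_reverse

    def test_proper_pair_bit_cleared_mate_fields_reset(self):
        r = read(100, "10M", flag=0x1 | 0x2 | 0x40).with_(
            rnext="chrQ", pnext=400, tlen=300
        )
        out = transform_read(r, build_index([fmap()]))
        assert out.flag & 0x1 and out.flag & 0x40 and not out.flag & 0x2
        assert out.rnext is None and out.pnext == -1 and out.tlen == 0


def random_map(rng, orientation):
    """A random gap-and-indel-riddled map over query [1000, ~1100)."""
    blocks = []
    q = 1000
    t = rng.randrange(2000, 3000)
    step = 1 if orientation == "forward" else -1
    for _ in range(rng.randint(1, 6)):
        length = rng.randint(1, 15)
        if orientation == "forward":
            blocks.append(MapBlock(q, t, length))
            t += length + rng.randint(0, 5)
        else:
            blocks.append(MapBlock(q, t, length))
            t -= length + rng.randint(0, 5)
        q += length + rng.randint(0, 4)
    return CoordinateMap("g", "chrQ", "chrT", orientation, blocks)


def random_read(rng, lo=980, hi=1120):
    ops = []
    pos = rng.randrange(lo, hi)
    if rng.random() < 0.2:
        ops.append(CigarOp("S", rng.randint(1, 4)))
    ops.append(CigarOp("M", rng.randint(1, 20)))
    for _ in range(rng.randint(0, 3)):
        code = rng.choice(["I", "D"])
        ops.append(CigarOp(code, rng.randint(1, 4)))
        ops.append(CigarOp("M", rng.randint(1, 20)))
    if rng.random() < 0.2:
        ops.append(CigarOp("S", rng.randint(1, 4)))
    qlen = sum(op.length for op in ops if op.code in "MIS=X")
    flag = 0x10 if rng.random() < 0.5 else 0
    bases = "".join(rng.choice("ACGT") for _ in range(qlen))
    return SamRecord("r", flag, "chrQ", pos, 30, ops, None, -1, 0,
                     bases, "I" * qlen, ())


class TestCompositionProperties:
    """Random-instance checks against the per-base composition oracle."""

    @pytest.mark.parametrize("orientation", ["forward", "reverse"])
    def test_output_pairs_equal_brute_force_composition(self, orientation):
        rng = random.Random(11)
        checked = 0
        for _ in range(400):
            cmap = random_map(rng, orientation)
            r = random_read(rng)
            idx = build_index([cmap])
            out = transform_read(r, idx)
            if not out.is_mapped:
                lift = cmap.lift
                pairs = composed_read_pairs(r, lift, flipped=False)
                assert len(pairs) == 0  # unmapped only when nothing lifts
                continue
            checked += 1
            flipped = out.is_reverse != r.is_reverse
            expected = composed_read_pairs(r, cmap.lift, flipped)
            actual = set(output_target_positions(out).items())
            assert actual == expected
            # CIGAR consumes exactly the stored sequence
            assert out.query_consumed() == len(out.seq)
            # M-base target positions strictly increase
            targets = [t for _, t in sorted(output_target_positions(out).items())]
            assert targets == sorted(targets)
            # sequence content follows the orientation change
            assert out.seq == (reverse_complement(r.seq) if flipped else r.seq)
        assert checked > 100

    def test_involution_identity_map(self):
        """An identity map fixes fully-covered reads, twice over."""
        from _oracle import read_query_positions

        ident = fmap(blocks=((100, 100, 50),), target="chrQ")
        idx = build_index([ident])
        rng = random.Random(5)
        n = 0
        for _ in range(200):
            r = random_read(rng, lo=100, hi=140)
            positions = read_query_positions(r).values()
            if not all(100 <= q < 150 for q in positions):
                continue
            n += 1
            out = transform_read(r, idx)
            assert (out.rname, out.pos, cigar_to_str(out.cigar), out.flag) == (
                "chrQ", r.pos, cigar_to_str(r.cigar), r.flag)
            back = transform_read(out, idx)
            assert (back.pos, cigar_to_str(back.cigar), back.seq) == (
                r.pos, cigar_to_str(r.cigar), r.seq)
        assert n > 30


class TestTransformFile:
    def test_empty_input_writes_header_only(self, tmp_path, dataset_settings):
        s = copy.copy(dataset_settings)
        empty = tmp_path / "empty.sam"
        empty.write_text("@HD\tVN:1.6\tSO:unknown\n")
        s.reads_sam = empty
        s.output_sam = tmp_path / "out.sam"
        stats = transform_file(s)
        assert (stats.n_input, stats.n_transformed, stats.n_unmapped_out,
                stats.n_passthrough_unmapped) == (0, 0, 0, 0)
        lines = s.output_sam.read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)
        assert sum(l.startswith("@SQ") for l in lines) == 2

    def test_record_conservation(self, tmp_path, dataset_settings):
        s = copy.copy(dataset_settings)
        s.output_sam = tmp_path / "out.sam"
        stats = transform_file(s)
        _, out_records = read_sam(s.output_sam)
        assert stats.n_input == len(out_records) == 5000
        assert (stats.n_transformed + stats.n_unmapped_out
                + stats.n_passthrough_unmapped) == stats.n_input
        assert sum(stats.per_gene.values()) == stats.n_transformed

    def test_parallel_output_byte_identical(self, tmp_path, dataset_settings):
        s1 = copy.copy(dataset_settings)
        s1.output_sam = tmp_path / "serial.sam"
        transform_file(s1)
        s4 = copy.copy(dataset_settings)
        s4.n_jobs = 4
        s4.output_sam = tmp_path / "parallel.sam"
        transform_file(s4)
        assert s1.output_sam.read_bytes() == s4.output_sam.read_bytes()
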