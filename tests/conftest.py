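"""Shared fixtures: simulated species pairs at the default study scale."""

from __future__ import annotations

import pytest
from hypothesis import settings as hyp_settings

from readlift.coordmap import build_coord_map, build_index
from readlift.formats import read_settings
from readlift.homology import scored_alignments
from readlift.regions import compute_regions, parse_region_header
from readlift.synthetic import (
    DEFAULTS,
    MutationModel,
    mutate_genome,
    plant_genes,
    random_genome,
    simulate_reads,
    truth_alignment_sam,
)

hyp_settings.register_profile("repro", deadline=None, derandomize=True)
hyp_settings.load_profile("repro")


@pytest.fixture(scope="session")
def sim_pair():
    """Default simulated pair: genomes, truth, annotation, regions, maps."""
    seed = DEFAULTS["seed"]
    genome = random_genome(DEFAULTS["chrom_lengths"], seed=seed)
    model = MutationModel(
        snp_rate=DEFAULTS["snp_rate"],
        ins_rate=DEFAULTS["ins_rate"],
        del_rate=DEFAULTS["del_rate"],
        max_indel_len=DEFAULTS["max_indel_len"],
        seed=seed + 1,
    )
    target, truth = mutate_genome(genome, model)
    features = plant_genes(
        genome,
        DEFAULTS["n_genes"],
        DEFAULTS["gene_length_range"],
        DEFAULTS["flank_gap"],
        seed=seed + 2,
    )
    regions = compute_regions(
        features,
        {rec.id: len(rec) for rec in genome},
        DEFAULTS["flank"],
        DEFAULTS["flank"],
    )
    gene_alns = truth_alignment_sam(regions, truth, genome)
    maps = [
        build_coord_map(aln, parse_region_header(aln.record.qname))
        for aln in scored_alignments(gene_alns)
    ]
    return {
        "genome": genome,
        "target": target,
        "truth": truth,
        "features": features,
        "regions": regions,
        "gene_alns": gene_alns,
        "maps": maps,
        "index": build_index(maps),
    }


@pytest.fixture(scope="session")
def sim_reads(sim_pair):
    return simulate_reads(
        sim_pair["genome"],
        sim_pair["regions"],
        read_length=DEFAULTS["read_length"],
        n_reads=DEFAULTS["n_reads"],
        seed=DEFAULTS["seed"] + 3,
        fraction_outside=DEFAULTS["fraction_outside"],
    )


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A full on-disk simulated dataset with settings.ini."""
    from readlift.synthetic import generate_dataset

    out = tmp_path_factory.mktemp("dataset")
    ini = generate_dataset(out, seed=DEFAULTS["seed"])
    return ini.parent


@pytest.fixture()
def dataset_settings(dataset_dir):
    return read_settings(dataset_dir / "settings.ini")
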