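import copy

import pytest

from subtelo import (
    SimulationConfig,
    align_chromosome_ends,
    all_vs_all_stats,
    assign_genes_to_subtelomeres,
    delineate_subtelomeres,
    find_all_telomeres,
    generate_genome,
)
from subtelo.cli import DEFAULT_CONFIG, run_demo

SEED = 1


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def genome(sim_config):
    """(ScaffoldSet, genes, truth) for the default synthetic genome."""
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def telomere_annotations(genome):
    scaffolds, _, _ = genome
    return find_all_telomeres(scaffolds)


@pytest.fixture(scope="session")
def subtel_pipeline(genome, telomere_annotations):
    """End-alignment blocks, regions, and the gene→region assignment."""
    scaffolds, genes, _ = genome
    blocks = align_chromosome_ends(scaffolds, telomere_annotations)
    regions = delineate_subtelomeres(blocks, telomere_annotations, scaffolds)
    assignment = assign_genes_to_subtelomeres(regions, genes)
    return blocks, regions, assignment


@pytest.fixture(scope="session")
def homology_stats(genome):
    _, genes, _ = genome
    return all_vs_all_stats({g.gene_id: g.protein_sequence for g in genes})


@pytest.fixture(scope="session")
def demo_metrics(tmp_path_factory):
    """Full pipeline demo on the default seeded genome."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["seed"] = SEED
    cfg["outdir"] = str(tmp_path_factory.mktemp("demo"))
    return run_demo(cfg)
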