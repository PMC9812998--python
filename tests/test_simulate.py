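import itertools

import numpy as np
import pytest

from subtelo import (
    SimulationConfig,
    SpeciesTree,
    generate_genome,
    mutate_cds,
    simulate_dollo,
    simulate_kaks_pairs,
    translate,
    write_genome_outputs,
)
from subtelo.simulate import random_cds, substream


def small_config(**kw) -> SimulationConfig:
    base = dict(
        seed=3,
        n_chromosomes=4,
        chromosome_length=70_000,
        subtelomere_block_length=12_000,
        n_ends_sharing_block=8,
        n_background_genes=40,
        polycistron_n_transcripts=2,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_generate_genome_plants_expected_objects():
    cfg = small_config()
    scaffolds, genes, truth = generate_genome(cfg)
    assert len(scaffolds) == 4
    assert len(truth.telomere_ends) == 8  # two per chromosome
    assert len(truth.subtelomere_intervals) == 8
    # 5-copy family => C(5,2)=10 pairs, 4-copy => 6
    sub_pairs = [p for p in truth.duplicate_pairs if p[2] == "subtelomeric"]
    int_pairs = [p for p in truth.duplicate_pairs if p[2] == "internal"]
    assert len(sub_pairs) == 10
    assert len(int_pairs) == 6
    # every planted gene resolves in the emitted coordinates
    ids = {g.gene_id for g in genes}
    assert truth.duplicated_genes <= ids
    assert truth.subtelomeric_genes <= ids


def test_zero_divergence_blocks_are_identical():
    cfg = small_config(block_divergence=0.0)
    scaffolds, _, truth = generate_genome(cfg)
    shared = []
    for (sid, end), (lo, hi) in sorted(truth.subtelomere_intervals.items()):
        seq = scaffolds[sid]
        # the shared zone is the interior-most part of the planted block
        if end == "left":
            shared.append(seq[lo + 2400:hi])
        else:
            shared.append(seq[lo:hi - 2400])
    assert len(set(shared)) == 1


def test_determinism_same_seed_same_bytes(tmp_path):
    cfg = small_config()
    out1 = tmp_path / "a"
    out2 = tmp_path / "b"
    for out in (out1, out2):
        sc, genes, truth = generate_genome(cfg)
        write_genome_outputs(out, sc, genes, truth)
    for name in ("genome.fasta", "genes.gff3", "proteins.faa", "transcripts.bed"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_different_seed_changes_genome():
    sc1, _, _ = generate_genome(small_config(seed=3))
    sc2, _, _ = generate_genome(small_config(seed=4))
    assert sc1.scaffolds != sc2.scaffolds


class TestMutateCds:
    def test_zero_rates_identity(self):
        cds = random_cds(100, substream(0, "x"))
        assert mutate_cds(cds, 0.0, 0.0, 7) == cds

    def test_synonymous_only_preserves_protein(self):
        cds = random_cds(200, substream(0, "y"))
        mut = mutate_cds(cds, 0.2, 0.0, 7)
        assert translate(mut) == translate(cds)
        assert mut != cds

    def test_nonsynonymous_rate_changes_expected_aa_count(self):
        # 300 codons at rate 0.2 → ≈60 amino-acid changes (binomial ±5σ)
        cds = random_cds(302, substream(0, "z"))
        mut = mutate_cds(cds, 0.0, 0.2, 11)
        diffs = sum(a != b for a, b in zip(translate(cds), translate(mut)))
        sd = np.sqrt(300 * 0.2 * 0.8)
        assert abs(diffs - 60) < 5 * sd

    def test_rejects_internal_stop(self):
        with pytest.raises(ValueError, match="internal stop"):
            mutate_cds("ATGTAAAAATAA", 0.1, 0.1, 0)

    def test_never_introduces_stops(self):
        cds = random_cds(150, substream(0, "w"))
        mut = mutate_cds(cds, 0.3, 0.3, 13)
        assert "*" not in translate(mut)


class TestSimulateDollo:
    tree = SpeciesTree.from_newick("((A,B),(C,D));")

    def test_zero_loss_prob_all_present_under_gain(self):
        gain = self.tree.label(self.tree.mrca(["A", "B"]))
        matrix, truths = simulate_dollo(self.tree, gain, 0.0, 20, seed=5)
        assert (matrix.data[["A", "B"]].to_numpy() == 1).all()
        assert (matrix.data[["C", "D"]].to_numpy() == 0).all()
        assert all(t.consistent for t in truths)

    def test_gain_at_leaf_is_singleton(self):
        matrix, truths = simulate_dollo(self.tree, "A", 0.5, 10, seed=5)
        assert (matrix.data["A"] == 1).all()
        assert matrix.data[["B", "C", "D"]].to_numpy().sum() == 0

    def test_cherry_loss_half_expectation(self):
        # loss_prob=0.5 on a cherry → ≈250/1000 families present in both
        cherry = SpeciesTree.from_newick("(A,B);")
        root = cherry.label(cherry.root)
        matrix, _ = simulate_dollo(cherry, root, 0.5, 1000, seed=5)
        both = int((matrix.data.sum(axis=1) == 2).sum())
        sd = np.sqrt(1000 * 0.25 * 0.75)
        assert abs(both - 250) < 5 * sd


def test_kaks_pairs_carry_regime_and_validate():
    pairs = simulate_kaks_pairs([(0.15, 0.02), (0.02, 0.15)], 5, 100, seed=2)
    assert len(pairs) == 10
    regimes = {p.regime for p in pairs}
    assert regimes == {"purifying", "positive"}
    for p in pairs:
        assert len(p.cds_a) == len(p.cds_b) == 300
        assert "*" not in translate(p.cds_b)


def test_config_validation():
    with pytest.raises(ValueError, match="exceed"):
        SimulationConfig(chromosome_length=10_000)
    with pytest.raises(ValueError, match="motif"):
        SimulationConfig(telomere_motif="ACG")
    with pytest.raises(ValueError, match="sharing"):
        SimulationConfig(n_ends_sharing_block=999)
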