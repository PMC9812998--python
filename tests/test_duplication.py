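from math import comb

import numpy as np
import pytest

from subtelo import (
    build_threshold_grid,
    detect_duplicates,
    fisher_exact,
    pairwise_protein_stats,
    stgd_report,
)
from subtelo.duplication import DuplicatePairSet, HomologyStats, all_vs_all_stats

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_protein(n, rng):
    return "".join(rng.choice(list(AA), size=n))


# ---------------------------------------------------------------------------
# pairwise stats
# ---------------------------------------------------------------------------

def test_identical_proteins_full_identity_and_coverage():
    rng = np.random.default_rng(0)
    p = _rand_protein(200, rng)
    ident, cov_a, cov_b, cols = pairwise_protein_stats(p, p)
    assert ident == 100.0
    assert cov_a == cov_b == 100.0
    assert cols == 200


def test_half_protein_coverage_asymmetry():
    rng = np.random.default_rng(1)
    p = _rand_protein(200, rng)
    ident, cov_a, cov_b, _ = pairwise_protein_stats(p, p[:100])
    assert cov_b > 95.0
    assert 45.0 <= cov_a <= 55.0
    assert ident > 95.0


def test_ten_percent_mutated_identity_near_ninety():
    rng = np.random.default_rng(2)
    p = list(_rand_protein(300, rng))
    q = p.copy()
    for i in rng.choice(300, size=30, replace=False):
        q[i] = rng.choice([a for a in AA if a != p[i]])
    ident, cov_a, cov_b, _ = pairwise_protein_stats("".join(p), "".join(q))
    assert 85.0 <= ident <= 95.0
    assert cov_a >= 95.0 and cov_b >= 95.0


def test_x_never_counts_as_match():
    # internal X aligns to itself but is not a match: 12 of 13 columns
    p = "ADKLEW" + "X" + "RNDCEQ"
    ident, *_ = pairwise_protein_stats(p, p)
    assert ident == pytest.approx(100 * 12 / 13)


def test_empty_protein_errors():
    with pytest.raises(ValueError, match="empty"):
        pairwise_protein_stats("", "ACDEF")


# ---------------------------------------------------------------------------
# threshold grid
# ---------------------------------------------------------------------------

def test_default_grid_has_25_cells_identity_major():
    grid = build_threshold_grid()
    assert len(grid) == 25
    assert grid[0] == (70, 70)
    assert grid[4] == (70, 90)
    assert grid[-1] == (90, 90)


@pytest.mark.parametrize(
    "kwargs,n",
    [
        (dict(id_min=70, id_max=70, cov_min=70, cov_max=70), 1),
        (dict(id_step=10, cov_step=10), 9),
    ],
)
def test_grid_sizes(kwargs, n):
    assert len(build_threshold_grid(**kwargs)) == n


def test_grid_rejects_inverted_or_nondividing_ranges():
    with pytest.raises(ValueError, match="inverted"):
        build_threshold_grid(id_min=90, id_max=70)
    with pytest.raises(ValueError, match="divide"):
        build_threshold_grid(id_step=7)


# ---------------------------------------------------------------------------
# duplicate detection
# ---------------------------------------------------------------------------

def test_planted_family_all_pairs_one_component(genome, homology_stats):
    _, _, truth = genome
    dup = detect_duplicates(homology_stats, (70, 70))
    fam5 = next(f for f in truth.families if len(f.gene_ids) == 5)
    pairs5 = {p for p in dup.pairs if p[0] in fam5.gene_ids}
    assert len(pairs5) == comb(5, 2)
    assert sorted(fam5.gene_ids) in [sorted(f) for f in dup.families]
    # two disjoint planted families → two components, no cross pairs
    assert len(dup.families) == len(truth.families)
    assert dup.genes == truth.duplicated_genes


def test_no_pair_passing_gives_empty_set(homology_stats):
    dup = detect_duplicates(homology_stats, (101, 101))
    assert dup.pairs == set() and dup.genes == set() and dup.families == []


def test_grid_monotonicity_nested_cells(homology_stats):
    """Raising either threshold never adds kept pairs."""
    grid = build_threshold_grid()
    kept = {cell: detect_duplicates(homology_stats, cell).pairs for cell in grid}
    for i1, c1 in grid:
        for i2, c2 in grid:
            if i2 >= i1 and c2 >= c1:
                assert kept[(i2, c2)] <= kept[(i1, c1)]


# ---------------------------------------------------------------------------
# STGD report
# ---------------------------------------------------------------------------

def _dupset(pairs):
    return DuplicatePairSet(cell=(70, 70), pairs=set(pairs))


def test_stgd_ratio_arithmetic():
    genes = {f"g{i}" for i in range(100)}
    subtel = {f"g{i}" for i in range(20)}
    # 10 duplicated genes, 6 subtelomeric
    pairs = [(f"g{2 * i}", f"g{2 * i + 1}") for i in range(3)]  # g0..g5 subtel
    pairs += [(f"g{50 + 2 * i}", f"g{51 + 2 * i}") for i in range(2)]
    rep = stgd_report(_dupset(pairs), subtel, genes)
    assert rep.n_duplicated == 10
    assert rep.stgd_ratio == pytest.approx(60.0)
    assert sum(rep.table[0]) == len(subtel)
    assert sum(rep.table[0]) + sum(rep.table[1]) == len(genes)


def test_stgd_ratio_all_subtelomeric_is_100():
    genes = {"a", "b", "c", "d"}
    rep = stgd_report(_dupset([("a", "b")]), {"a", "b"}, genes)
    assert rep.stgd_ratio == pytest.approx(100.0)


def test_stgd_no_duplicates_reports_missing():
    rep = stgd_report(_dupset([]), {"a"}, {"a", "b"})
    assert rep.stgd_ratio is None and rep.fisher_p is None


def test_stgd_ratio_invariant_to_relabeling(genome, homology_stats):
    _, _, truth = genome
    dup = detect_duplicates(homology_stats, (70, 70))
    genes = {g for s in homology_stats for g in (s.gene_a, s.gene_b)} | truth.subtelomeric_genes | dup.genes
    rep = stgd_report(dup, truth.subtelomeric_genes, genes)
    relabel = {g: f"x{i:04d}" for i, g in enumerate(sorted(genes))}
    dup2 = DuplicatePairSet(
        cell=dup.cell,
        pairs={tuple(sorted((relabel[a], relabel[b]))) for a, b in dup.pairs},
    )
    rep2 = stgd_report(
        dup2, {relabel[g] for g in truth.subtelomeric_genes}, set(relabel.values())
    )
    assert rep2.stgd_ratio == rep.stgd_ratio


# ---------------------------------------------------------------------------
# Fisher's exact test vs exhaustive enumeration
# ---------------------------------------------------------------------------

def fisher_by_enumeration(table):
    """Two-sided p by summing hypergeometric probabilities over all tables
    with the observed margins whose probability ≤ the observed one."""
    (a, b), (c, d) = table
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0

    def prob(x):
        return comb(r1, x) * comb(r2, k - x) / comb(n, k)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, k - r2), min(r1, k) + 1)
        if prob(x) <= p_obs * (1 + 1e-7)
    )


def test_fisher_degenerate_table_is_one():
    assert fisher_exact([[0, 0], [0, 0]]) == 1.0
    assert fisher_exact([[3, 2], [0, 0]]) == 1.0


def test_fisher_diagonal_table_exact_value():
    assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)


def test_fisher_rejects_negative_or_fractional():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [2, 3]])


def test_fisher_matches_enumeration_on_random_tables():
    """100 random 2×2 tables with N ≤ 40: exact agreement with enumeration."""
    rng = np.random.default_rng(12345)
    for _ in range(100):
        n = int(rng.integers(1, 41))
        cells = rng.multinomial(n, [0.25] * 4)
        table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
        assert fisher_exact(table) == pytest.approx(
            fisher_by_enumeration(table), rel=1e-6, abs=1e-12
        ), table
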