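"""Recent gene-duplication detection over an identity/coverage threshold grid.

All-vs-all local protein alignment yields per-pair percent identity and
query/subject coverage; a pair is a recent duplicate in a grid cell when
identity and both coverages meet that cell's thresholds (the canonical grid
spans 70–90% in 5% steps on both axes, 25 cells). Duplicate families are the
connected components of the kept-pair graph. The subtelomeric gene
duplication (STGD) ratio is the percentage of duplicated genes that lie in
subtelomeric regions, and a two-sided Fisher's exact test on the
{subtelomeric, non-subtelomeric} × {duplicated, non-duplicated} table scores
the association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

log = logging.getLogger("subtelo")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class HomologyStats:
    """Local-alignment statistics for one unordered protein pair.

    Stored once with gene_a < gene_b lexicographically; coverage_a/coverage_b
    are the aligned fraction of each sequence (the query/subject coverages of
    a symmetric search).
    """

    gene_a: str
    gene_b: str
    identity: float  # percent, gap columns in the denominator
    coverage_a: float  # percent of gene_a covered by the aligned span
    coverage_b: float
    alignment_length: int

    @property
    def query_coverage(self) -> float:
        return self.coverage_a

    @property
    def subject_coverage(self) -> float:
        return self.coverage_b


_aligner: Optional[Align.PairwiseAligner] = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner()
        _aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _aligner.mode = "local"
        _aligner.open_gap_score = -11.0
        _aligner.extend_gap_score = -1.0
    return _aligner


def pairwise_protein_stats(protein_a: str, protein_b: str) -> tuple[float, float, float, int]:
    """Align two proteins locally and report (identity%, cov_a%, cov_b%, columns).

    Identity uses alignment columns (gap columns included) as the
    denominator; 'X' never counts as a match. Coverage is the aligned span on
    each sequence divided by its length.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    for seq, name in ((protein_a, "a"), (protein_b, "b")):
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {name} has letters outside the alphabet: {sorted(bad)}")
    aln = _get_aligner().align(protein_a, protein_b)
    if len(aln) == 0:
        return 0.0, 0.0, 0.0, 0
    best = aln[0]
    seg_a, seg_b = best.aligned
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(seg_a, seg_b):
        aligned_cols += a1 - a0
        for x, y in zip(protein_a[a0:a1], protein_b[b0:b1]):
            if x == y and x != "X":
                matches += 1
    # gap columns between consecutive aligned segments
    gap_cols = 0
    for i in range(1, len(seg_a)):
        gap_cols += (seg_a[i][0] - seg_a[i - 1][1]) + (seg_b[i][0] - seg_b[i - 1][1])
    columns = aligned_cols + gap_cols
    if columns == 0:
        return 0.0, 0.0, 0.0, 0
    span_a = seg_a[-1][1] - seg_a[0][0]
    span_b = seg_b[-1][1] - seg_b[0][0]
    identity = 100.0 * matches / columns
    cov_a = 100.0 * span_a / len(protein_a)
    cov_b = 100.0 * span_b / len(protein_b)
    return identity, cov_a, cov_b, columns


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_stats(
    proteome: dict[str, str],
    prefilter_k: int = 5,
    prefilter_min_shared: int = 3,
) -> list[HomologyStats]:
    """All-vs-all homology statistics over a proteome (self-pairs excluded).

    A cheap shared-k-mer prefilter skips pairs that cannot reach the grid's
    identity range; pairs sharing ≥ ``prefilter_min_shared`` exact k-mers (or
    involving a sequence shorter than 4k) are aligned. Set
    ``prefilter_min_shared=0`` to align every pair.
    """
    ids = sorted(proteome)
    kmers = {g: _kmer_set(proteome[g], prefilter_k) for g in ids}
    out: list[HomologyStats] = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            if prefilter_min_shared > 0:
                short = min(len(proteome[ga]), len(proteome[gb])) < 4 * prefilter_k
                if not short and len(kmers[ga] & kmers[gb]) < prefilter_min_shared:
                    continue
            ident, cov_a, cov_b, cols = pairwise_protein_stats(proteome[ga], proteome[gb])
            if cols == 0:
                continue
            out.append(HomologyStats(ga, gb, ident, cov_a, cov_b, cols))
    return out


def build_threshold_grid(
    id_min: float = 70,
    id_max: float = 90,
    id_step: float = 5,
    cov_min: float = 70,
    cov_max: float = 90,
    cov_step: float = 5,
) -> list[tuple[float, float]]:
    """Full identity × coverage Cartesian grid, identity-major order."""
    for lo, hi, step in ((id_min, id_max, id_step), (cov_min, cov_max, cov_step)):
        if hi < lo:
            raise ValueError(f"inverted range {lo}..{hi}")
        if step <= 0 or round((hi - lo) / step, 9) % 1 != 0:
            raise ValueError(f"step {step} does not divide range {lo}..{hi}")
    n_id = int(round((id_max - id_min) / id_step)) + 1
    n_cov = int(round((cov_max - cov_min) / cov_step)) + 1
    return [
        (id_min + i * id_step, cov_min + j * cov_step)
        for i in range(n_id)
        for j in range(n_cov)
    ]


@dataclass
class DuplicatePairSet:
    """Gene pairs passing one (identity, coverage) grid cell, plus families."""

    cell: tuple[float, float]
    pairs: set[tuple[str, str]]
    genes: set[str] = field(default_factory=set)
    families: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = {g for p in self.pairs for g in p}
        if not self.families and self.pairs:
            g = nx.Graph()
            g.add_edges_from(self.pairs)
            self.families = sorted(
                (set(c) for c in nx.connected_components(g)), key=lambda s: sorted(s)[0]
            )


def detect_duplicates(
    stats: Iterable[HomologyStats], cell: tuple[float, float]
) -> DuplicatePairSet:
    """Keep pairs meeting the cell's identity and both-coverage thresholds."""
    id_thr, cov_thr = cell
    pairs = {
        (s.gene_a, s.gene_b)
        for s in stats
        if s.identity >= id_thr and s.coverage_a >= cov_thr and s.coverage_b >= cov_thr
    }
    return DuplicatePairSet(cell=cell, pairs=pairs)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test p-value for a 2×2 count table.

    The p-value is the total hypergeometric probability of all tables with
    the observed margins whose probability does not exceed the observed
    table's (ties within ~1e-7 relative tolerance included). Degenerate
    margins give p = 1 by convention.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"table cells must be non-negative integers, got {table}")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        log.debug("fisher_exact: zero margin in %s, returning p=1", table)
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


@dataclass
class STGDReport:
    """Subtelomeric gene duplication summary at one grid cell."""

    cell: tuple[float, float]
    n_genes: int
    n_subtelomeric: int
    n_duplicated: int
    n_duplicated_subtelomeric: int
    stgd_ratio: Optional[float]  # percent; None when nothing is duplicated
    table: list[list[int]]  # {subtel, non-subtel} × {dup, non-dup}
    fisher_p: Optional[float]


def stgd_report(
    dup: DuplicatePairSet,
    subtelomeric_genes: set[str],
    all_genes: set[str],
) -> STGDReport:
    """STGD ratio and duplication×location contingency table for one cell."""
    if not dup.genes <= all_genes:
        raise ValueError("duplicated genes outside the gene universe")
    if not subtelomeric_genes <= all_genes:
        raise ValueError("subtelomeric genes outside the gene universe")
    n_dup = len(dup.genes)
    n_dup_sub = len(dup.genes & subtelomeric_genes)
    n_sub = len(subtelomeric_genes)
    table = [
        [n_dup_sub, n_sub - n_dup_sub],
        [n_dup - n_dup_sub, len(all_genes) - n_sub - (n_dup - n_dup_sub)],
    ]
    if n_dup == 0:
        log.warning("no duplicated genes at cell %s; STGD ratio undefined", dup.cell)
        return STGDReport(dup.cell, len(all_genes), n_sub, 0, 0, None, table, None)
    ratio = 100.0 * n_dup_sub / n_dup
    return STGDReport(
        dup.cell, len(all_genes), n_sub, n_dup, n_dup_sub, ratio, table, fisher_exact(table)
    )


def grid_report(
    stats: Sequence[HomologyStats],
    subtelomeric_genes: set[str],
    all_genes: set[str],
    grid: Optional[list[tuple[float, float]]] = None,
) -> pd.DataFrame:
    """STGD report across every grid cell, one row per cell."""
    if grid is None:
        grid = build_threshold_grid()
    rows = []
    for cell in grid:
        rep = stgd_report(detect_duplicates(stats, cell), subtelomeric_genes, all_genes)
        rows.append(
            {
                "identity_thr": cell[0],
                "coverage_thr": cell[1],
                "n_duplicated": rep.n_duplicated,
                "n_duplicated_subtelomeric": rep.n_duplicated_subtelomeric,
                "stgd_ratio": rep.stgd_ratio,
                "fisher_p": rep.fisher_p,
            }
        )
    return pd.DataFrame(rows)
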