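"""Collinear (synteny) block detection between two annotated genomes.

Homologous gene pairs (anchors) are chained per scaffold pair and
orientation by longest-chain dynamic programming: a chain is a run of
anchors whose gene ranks increase in both genomes (or decrease in genome b
for inverted blocks) with at most ``max_gap`` intervening genes between
consecutive anchors on either side. Chains are extracted best-first, each
anchor used at most once, and kept when they reach ``min_block`` anchors —
the classic MCScanX-style parameters (block ≥ 5 genes, gap ≤ 25 genes).
Chain score is the anchor count, ties broken toward fewer rank gaps.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence, Union

from .core import GeneModel
from .duplication import HomologyStats

log = logging.getLogger("subtelo")

AnchorInput = Union[tuple[str, str], HomologyStats]


@dataclass
class CollinearBlock:
    anchors: list[tuple[str, str]]  # ordered (gene_a, gene_b) pairs
    orientation: str  # 'same' | 'inverted'
    scaffold_a: str
    scaffold_b: str

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _ranks(genes: Sequence[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene_id → (scaffold, rank along scaffold by start coordinate)."""
    by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold_id].append(g)
    out: dict[str, tuple[str, int]] = {}
    for sid, gs in by_scaffold.items():
        for rank, g in enumerate(sorted(gs, key=lambda g: g.start)):
            out[g.gene_id] = (sid, rank)
    return out


def _normalize_pairs(
    homolog_pairs: Sequence[AnchorInput],
) -> list[tuple[str, str, float]]:
    out = []
    for p in homolog_pairs:
        if isinstance(p, HomologyStats):
            out.append((p.gene_a, p.gene_b, p.identity))
        else:
            a, b = p
            out.append((a, b, 100.0))
    return out


def _collapse_tandem(
    pairs: list[tuple[str, str, float]],
    rank_a: dict[str, tuple[str, int]],
    rank_b: dict[str, tuple[str, int]],
) -> list[tuple[str, str, float]]:
    """Keep the best pair per tandem cluster of a gene's partners.

    For each gene, partners on the same scaffold with consecutive ranks are
    a tandem cluster; only the highest-scoring pair of each cluster is kept,
    so a tandem array cannot inflate a block. Applied on both sides.
    """

    def one_side(pairs, key_gene, key_partner, rank_partner):
        grouped: dict[str, list[tuple[str, str, float]]] = defaultdict(list)
        for p in pairs:
            grouped[key_gene(p)].append(p)
        kept = []
        for _, ps in sorted(grouped.items()):
            ps.sort(key=lambda p: rank_partner[key_partner(p)])
            cluster: list[tuple[str, str, float]] = []
            prev = None
            for p in ps:
                sid, r = rank_partner[key_partner(p)]
                if prev is not None and (sid != prev[0] or r > prev[1] + 1):
                    kept.append(max(cluster, key=lambda q: q[2]))
                    cluster = []
                cluster.append(p)
                prev = (sid, r)
            if cluster:
                kept.append(max(cluster, key=lambda q: q[2]))
        return kept

    pairs = one_side(pairs, lambda p: p[0], lambda p: p[1], rank_b)
    pairs = one_side(pairs, lambda p: p[1], lambda p: p[0], rank_a)
    return pairs


def _best_chain(
    anchors: list[tuple[int, int, int]], orientation: str, max_gap: int
) -> list[int]:
    """Longest chain over (rank_a, rank_b, idx) anchors; returns anchor idxs.

    Score is anchor count; ties prefer fewer total rank gaps. O(n²) DP.
    """
    sign = 1 if orientation == "same" else -1
    pts = sorted(anchors, key=lambda t: (t[0], sign * t[1]))
    n = len(pts)
    best_len = [1] * n
    best_gap = [0] * n
    parent = [-1] * n
    for i in range(n):
        ra, rb, _ = pts[i]
        for j in range(i):
            qa, qb, _ = pts[j]
            if qa >= ra:
                continue
            db = (rb - qb) * sign
            if db <= 0:
                continue
            if ra - qa > max_gap + 1 or db > max_gap + 1:
                continue
            gap = best_gap[j] + (ra - qa - 1) + (db - 1)
            cand = (best_len[j] + 1, -gap)
            if cand > (best_len[i], -best_gap[i]):
                best_len[i], best_gap[i] = cand[0], -cand[1]
                parent[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -best_gap[i]))
    chain = []
    while end != -1:
        chain.append(pts[end][2])
        end = parent[end]
    return chain[::-1]


def find_collinear_blocks(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    homolog_pairs: Sequence[AnchorInput],
    min_block: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Maximal collinear chains of homologous gene pairs between two genomes."""
    rank_a = _ranks(genes_a)
    rank_b = _ranks(genes_b)
    pairs = [
        p for p in _normalize_pairs(homolog_pairs)
        if p[0] in rank_a and p[1] in rank_b
    ]
    pairs = _collapse_tandem(pairs, rank_a, rank_b)

    by_scafpair: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    for a, b, _ in pairs:
        by_scafpair[(rank_a[a][0], rank_b[b][0])].append((a, b))

    blocks: list[CollinearBlock] = []
    for (sa, sb), anchor_genes in sorted(by_scafpair.items()):
        free = list(anchor_genes)
        while free:
            coords = [
                (rank_a[a][1], rank_b[b][1], i) for i, (a, b) in enumerate(free)
            ]
            best: tuple[int, str, list[int]] | None = None
            for orientation in ("same", "inverted"):
                chain = _best_chain(coords, orientation, max_gap)
                if best is None or len(chain) > best[0]:
                    best = (len(chain), orientation, chain)
            if best is None or best[0] < min_block:
                break
            _, orientation, chain = best
            chain_genes = [free[i] for i in chain]
            blocks.append(CollinearBlock(chain_genes, orientation, sa, sb))
            used = set(chain)
            free = [g for i, g in enumerate(free) if i not in used]
    return blocks


def collinearity_fraction(
    blocks: Sequence[CollinearBlock],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
) -> dict[str, float]:
    """Percent of each genome's genes covered by ≥1 collinear block."""
    if not genes_a or not genes_b:
        raise ValueError("empty genome")
    in_a = {a for blk in blocks for a, _ in blk.anchors}
    in_b = {b for blk in blocks for _, b in blk.anchors}
    frac_a = 100.0 * len(in_a) / len(genes_a)
    frac_b = 100.0 * len(in_b) / len(genes_b)
    return {"frac_a": frac_a, "frac_b": frac_b, "frac_mean": (frac_a + frac_b) / 2.0}


def intersect_collinear_gene_sets(covered_sets: Sequence[set[str]]) -> set[str]:
    """Genes collinear in every pairwise comparison (multi-genome summary)."""
    if not covered_sets:
        return set()
    out = set(covered_sets[0])
    for s in covered_sets[1:]:
        out &= s
    return out
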