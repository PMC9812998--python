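"""Conserved telomere-proximal (subtelomeric) region delineation.

Chromosome ends within one genome are compared against each other: terminal
windows are aligned by exact k-mer seeding, same-diagonal chaining and
ungapped X-drop extension on both strands. Per end, the supporting alignment
blocks are merged (small gaps bridged), anchored at the terminus, and
clipped to a maximum extent to form the subtelomeric region, to which genes
are then assigned by fractional span overlap.

The seeding/chaining aligner assumes ends diverge mostly by substitution
(small indels are tolerated as block splits that the per-end merge bridges);
it is not a general-purpose genome aligner.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import GeneModel, ScaffoldSet, reverse_complement
from .telomeres import TelomereAnnotation

log = logging.getLogger("subtelo")

End = tuple[str, str]  # (scaffold_id, 'left'|'right')


@dataclass
class EndAlignmentBlock:
    """One aligned block between two terminal windows (genomic coordinates)."""

    end_a: End
    interval_a: tuple[int, int]
    end_b: End
    interval_b: tuple[int, int]
    identity: float  # percent
    length: int
    strand: str  # '+' same strand, '-' reverse complement


@dataclass
class SubtelomereRegion:
    scaffold_id: str
    end: str
    interval: tuple[int, int]  # terminus-anchored, 0-based half-open
    support: int  # number of distinct partner ends
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


# ---------------------------------------------------------------------------
# Window alignment
# ---------------------------------------------------------------------------

def _window(seq: str, end: str, window_bp: int) -> tuple[str, int]:
    """Terminal window sequence and its genomic start offset."""
    if len(seq) < window_bp:
        log.debug("scaffold shorter than end window; truncating to %d bp", len(seq))
        window_bp = len(seq)
    if end == "left":
        return seq[:window_bp], 0
    return seq[len(seq) - window_bp:], len(seq) - window_bp


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return dict(index)


def _seed_diagonals(
    index_a: dict[str, list[int]], wb: str, k: int, max_kmer_hits: int = 10
) -> dict[int, list[int]]:
    """Exact k-mer hits grouped by diagonal (pos_a − pos_b), keyed by pos_b."""
    diags: dict[int, list[int]] = defaultdict(list)
    for j in range(len(wb) - k + 1):
        hits = index_a.get(wb[j:j + k])
        if hits is None or len(hits) > max_kmer_hits:
            continue
        for i in hits:
            diags[i - j].append(j)
    return diags


def _extend_ungapped(
    wa: str, wb: str, diag: int, b_lo: int, b_hi: int, xdrop: int = 15
) -> tuple[int, int]:
    """X-drop extension of a seeded run on one diagonal; returns b-range."""
    # leftward
    score = best = 0
    j = b_lo - 1
    best_lo = b_lo
    while j >= 0 and 0 <= j + diag and j + diag < len(wa):
        score += 1 if wa[j + diag] == wb[j] else -3
        if score > best:
            best, best_lo = score, j
        if best - score > xdrop:
            break
        j -= 1
    # rightward
    score = best = 0
    j = b_hi
    best_hi = b_hi
    while j < len(wb) and j + diag < len(wa):
        score += 1 if wa[j + diag] == wb[j] else -3
        if score > best:
            best, best_hi = score, j + 1
        if best - score > xdrop:
            break
        j += 1
    return best_lo, best_hi


def _align_windows(
    wa: str, wb: str, seed_k: int, min_block_len: int, min_identity: float,
    seed_gap: int = 400, index_a: Optional[dict[str, list[int]]] = None,
) -> list[tuple[int, int, int, int, float]]:
    """Aligned blocks between two windows as (a0, a1, b0, b1, identity%)."""
    if index_a is None:
        index_a = _kmer_index(wa, seed_k)
    out = []
    for diag, positions in _seed_diagonals(index_a, wb, seed_k).items():
        positions.sort()
        # cluster seed positions separated by ≤ seed_gap on this diagonal
        clusters: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            if p - clusters[-1][-1] <= seed_gap:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            b_lo, b_hi = _extend_ungapped(wa, wb, diag, cl[0], cl[-1] + seed_k)
            length = b_hi - b_lo
            if length < min_block_len:
                continue
            matches = sum(
                1 for j in range(b_lo, b_hi) if wa[j + diag] == wb[j]
            )
            identity = 100.0 * matches / length
            if identity < min_identity:
                continue
            out.append((b_lo + diag, b_hi + diag, b_lo, b_hi, identity))
    # drop blocks nested in a longer block on a nearby diagonal
    out.sort(key=lambda t: -(t[1] - t[0]))
    kept: list[tuple[int, int, int, int, float]] = []
    for blk in out:
        if any(
            blk[0] >= k[0] and blk[1] <= k[1] and blk[2] >= k[2] and blk[3] <= k[3]
            for k in kept
        ):
            continue
        kept.append(blk)
    return kept


def align_chromosome_ends(
    scaffolds: ScaffoldSet,
    telomeres: Optional[list[TelomereAnnotation]] = None,
    end_window_bp: int = 50_000,
    seed_k: int = 15,
    min_block_len: int = 500,
    min_identity: float = 70.0,
) -> list[EndAlignmentBlock]:
    """Compare all pairs of terminal windows within a genome, both strands.

    When telomere annotations are given, only telomere-bearing ends are
    compared; otherwise every scaffold contributes both ends. Symmetric
    (a,b)/(b,a) duplicates are collapsed by comparing each unordered window
    pair once.
    """
    if end_window_bp < min_block_len:
        raise ValueError("end_window_bp must be at least min_block_len")
    if telomeres is not None:
        ends: list[End] = sorted({(t.scaffold_id, t.end) for t in telomeres})
    else:
        ends = [(sid, e) for sid in scaffolds.ids() for e in ("left", "right")]
    windows = {
        e: _window(scaffolds[e[0]], e[1], end_window_bp) for e in ends
    }
    indexes = {e: _kmer_index(windows[e][0], seed_k) for e in ends}
    blocks: list[EndAlignmentBlock] = []
    for i, ea in enumerate(ends):
        wa, off_a = windows[ea]
        for eb in ends[i + 1:]:
            if eb[0] == ea[0] and eb[1] == ea[1]:
                continue
            wb, off_b = windows[eb]
            for strand in "+-":
                wb_s = wb if strand == "+" else reverse_complement(wb)
                for a0, a1, b0, b1, ident in _align_windows(
                    wa, wb_s, seed_k, min_block_len, min_identity,
                    index_a=indexes[ea],
                ):
                    if strand == "-":
                        b0, b1 = len(wb) - b1, len(wb) - b0
                    # two windows of one short scaffold can overlap; a block
                    # covering the same genomic span is a self-match, not
                    # conserved end homology
                    if ea[0] == eb[0]:
                        ga = (off_a + a0, off_a + a1)
                        gb = (off_b + b0, off_b + b1)
                        if min(ga[1], gb[1]) > max(ga[0], gb[0]):
                            continue
                    blocks.append(
                        EndAlignmentBlock(
                            end_a=ea,
                            interval_a=(off_a + a0, off_a + a1),
                            end_b=eb,
                            interval_b=(off_b + b0, off_b + b1),
                            identity=ident,
                            length=a1 - a0,
                            strand=strand,
                        )
                    )
    return blocks


# ---------------------------------------------------------------------------
# Region delineation
# ---------------------------------------------------------------------------

def _merge_intervals(
    intervals: list[tuple[int, int]], gap: int
) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def delineate_subtelomeres(
    blocks: list[EndAlignmentBlock],
    telomeres: list[TelomereAnnotation],
    scaffolds: ScaffoldSet,
    max_extent: int = 30_000,
    min_support: int = 1,
    merge_gap: int = 2_000,
    emit_bare_ends: bool = False,
    flank_bp: int = 5_000,
) -> list[SubtelomereRegion]:
    """Call one terminus-anchored subtelomeric region per supported end.

    Block intervals on each end are merged (gaps ≤ ``merge_gap`` bridged),
    anchored at the terminus and clipped to ``max_extent``. ``support`` is
    the number of distinct partner ends; ends with fewer than ``min_support``
    partners are dropped. With ``emit_bare_ends``, a telomere-bearing end
    with no conserved block still yields a region spanning the telomere plus
    ``flank_bp``.
    """
    by_end: dict[End, list[tuple[int, int]]] = defaultdict(list)
    partners: dict[End, set[End]] = defaultdict(set)
    for blk in blocks:
        by_end[blk.end_a].append(blk.interval_a)
        by_end[blk.end_b].append(blk.interval_b)
        partners[blk.end_a].add(blk.end_b)
        partners[blk.end_b].add(blk.end_a)

    tel_by_end = {(t.scaffold_id, t.end): t for t in telomeres}
    regions: list[SubtelomereRegion] = []
    all_ends = sorted(set(by_end) | (set(tel_by_end) if emit_bare_ends else set()))
    for end in all_ends:
        sid, side = end
        length = len(scaffolds[sid])
        intervals = _merge_intervals(by_end.get(end, []), merge_gap)
        support = len(partners.get(end, ()))
        if intervals and support >= min_support:
            lo = min(s for s, _ in intervals)
            hi = max(e for _, e in intervals)
        elif emit_bare_ends and end in tel_by_end:
            t = tel_by_end[end]
            lo, hi = t.span[0], t.span[1] + flank_bp
            support = 0
        else:
            continue
        # anchor at the terminus and clip to max_extent
        if side == "left":
            interval = (0, min(hi, max_extent))
        else:
            interval = (max(lo, length - max_extent), length)
        regions.append(SubtelomereRegion(sid, side, interval, support))
    return regions


def assign_genes_to_subtelomeres(
    regions: Sequence[SubtelomereRegion],
    genes: Sequence[GeneModel],
    min_overlap_frac: float = 0.5,
) -> dict[str, SubtelomereRegion]:
    """Assign each gene to at most one region by fractional span overlap.

    A gene is a member when at least ``min_overlap_frac`` of its genomic span
    overlaps the region; with several candidates the larger overlap wins and
    ties go to the region whose terminus is closer.
    """
    by_scaffold: dict[str, list[SubtelomereRegion]] = defaultdict(list)
    for r in regions:
        by_scaffold[r.scaffold_id].append(r)
    assignment: dict[str, SubtelomereRegion] = {}
    for gene in genes:
        gs, ge = gene.span
        glen = ge - gs
        best = None  # (overlap, -distance_to_terminus, region)
        for r in by_scaffold.get(gene.scaffold_id, ()):
            ov = min(ge, r.interval[1]) - max(gs, r.interval[0])
            if ov <= 0 or ov / glen < min_overlap_frac:
                continue
            terminus = r.interval[0] if r.end == "left" else r.interval[1]
            dist = min(abs(gs - terminus), abs(ge - terminus))
            if best is None or (ov, -dist) > (best[0], best[1]):
                best = (ov, -dist, r)
        if best is not None:
            assignment[gene.gene_id] = best[2]
            best[2].genes.append(gene.gene_id)
    return assignment
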