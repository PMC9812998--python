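"""Polycistronic transcript calling from transcript-to-genome alignments.

A transcript is polycistronic when the union of its exon blocks completely
covers (every base of) the CDS span of at least two genes on its own strand.
Coverage is measured against the CDS span — first to last coding base —
because the gene models here are CDS-defined; spliced alignments are fine
since only the covering union matters, not contiguity.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .core import GeneModel, TranscriptAlignment

log = logging.getLogger("subtelo")


@dataclass
class PolycistronCall:
    transcript_id: str
    gene_ids: list[str]  # completely covered genes, ordered along the scaffold

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _merge_blocks(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:  # abutting blocks merge
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def call_polycistronic(
    alignments: Sequence[TranscriptAlignment],
    genes: Sequence[GeneModel],
    min_genes: int = 2,
) -> list[PolycistronCall]:
    """Transcripts whose exon-block union fully covers ≥ min_genes same-strand genes."""
    by_loc: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_loc[(g.scaffold_id, g.strand)].append(g)
    for gs in by_loc.values():
        gs.sort(key=lambda g: g.start)

    calls: list[PolycistronCall] = []
    for aln in alignments:
        merged = _merge_blocks(aln.blocks)
        covered: list[str] = []
        for g in by_loc.get((aln.scaffold_id, aln.strand), ()):
            s, e = g.span
            if any(ms <= s and e <= me for ms, me in merged):
                covered.append(g.gene_id)
        if len(covered) >= min_genes:
            calls.append(PolycistronCall(aln.transcript_id, covered))
    return calls


def polycistronic_gene_fraction(
    calls: Sequence[PolycistronCall], genes: Sequence[GeneModel]
) -> float:
    """Percent of genes appearing in at least one polycistronic call."""
    if not genes:
        raise ValueError("no genes")
    covered = {g for c in calls for g in c.gene_ids}
    return 100.0 * len(covered) / len(genes)
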