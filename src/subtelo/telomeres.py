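"""Terminal tandem-repeat (telomere) detection and scaffold classification.

Telomeric arrays are short-period (typically 4–12 bp) tandem repeats anchored
at scaffold termini. For each terminus the detector scans a terminal window
for the period maximizing the matched tandem span under a per-copy mismatch
budget, and reports the consensus motif as the lexicographically smallest
rotation over both strands so that every rotation/strand of the same repeat
yields an identical motif string. Scaffolds are classified
telomere-to-telomere (T2T), single-end, or telomere-free.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .core import ScaffoldSet, reverse_complement

log = logging.getLogger("subtelo")


@dataclass
class TelomereAnnotation:
    scaffold_id: str
    end: str  # 'left' | 'right'
    motif: str  # canonical rotation over both strands
    copy_number: float  # matched span / period (fractional copies allowed)
    span: tuple[int, int]  # 0-based half-open, genomic coordinates


def canonical_motif(motif: str) -> str:
    """Smallest rotation of the motif or its reverse complement."""
    rc = reverse_complement(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _scan_left(window: str, period: int, offset: int, max_mismatch_frac: float):
    """Greedy tandem extension of window[offset:offset+period] to the right.

    Returns (matched_span, n_full_copies, copies) or None if the template
    runs past the window.
    """
    if offset + period > len(window):
        return None
    template = window[offset:offset + period]
    budget = int(max_mismatch_frac * period)
    copies = [template]
    i = offset + period
    while i + period <= len(window):
        copy = window[i:i + period]
        if _hamming(copy, template) <= budget:
            copies.append(copy)
            i += period
        else:
            break
    # partial trailing copy: longest exactly matching template prefix
    partial = 0
    while i + partial < len(window) and partial < period and window[i + partial] == template[partial]:
        partial += 1
    span = (i + partial) - offset
    return span, len(copies), copies


def find_terminal_repeats(
    scaffold_id: str,
    sequence: str,
    window_bp: int = 3000,
    motif_len_range: tuple[int, int] = (4, 12),
    min_copies: float = 8.0,
    max_mismatch_frac: float = 0.2,
    max_offset: int = 50,
) -> list[TelomereAnnotation]:
    """Detect telomeric tandem arrays at both termini of one scaffold.

    For each terminus, every candidate period in ``motif_len_range`` and
    array start within ``max_offset`` bp of the terminus is tried; the
    candidate with the largest matched span wins, ties broken toward the
    smaller period (so a 6-mer array is not reported as a 12-mer) and then
    the smaller offset. An annotation is emitted when the fractional copy
    number reaches ``min_copies``.
    """
    pmin, pmax = motif_len_range
    if window_bp > len(sequence):
        window_bp = len(sequence)
    if window_bp < pmax:
        raise ValueError(
            f"window ({window_bp} bp) shorter than the longest motif ({pmax} bp)"
        )
    out: list[TelomereAnnotation] = []
    for end in ("left", "right"):
        window = sequence[:window_bp] if end == "left" else reverse_complement(
            sequence[len(sequence) - window_bp:]
        )
        best = None  # (-span, period, offset, copies)
        for period in range(pmin, pmax + 1):
            for offset in range(0, max_offset + 1):
                hit = _scan_left(window, period, offset, max_mismatch_frac)
                if hit is None:
                    continue
                span, n_full, copies = hit
                cand = (-span, period, offset, copies)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is None:
            continue
        span, period, offset, copies = -best[0], best[1], best[2], best[3]
        copy_number = span / period
        if copy_number < min_copies:
            continue
        consensus = "".join(
            Counter(col).most_common(1)[0][0] for col in zip(*copies)
        )
        if end == "left":
            genomic = (offset, offset + span)
        else:
            genomic = (len(sequence) - offset - span, len(sequence) - offset)
        out.append(
            TelomereAnnotation(
                scaffold_id=scaffold_id,
                end=end,
                motif=canonical_motif(consensus),
                copy_number=copy_number,
                span=genomic,
            )
        )
    return out


def find_all_telomeres(scaffolds: ScaffoldSet, **kwargs) -> list[TelomereAnnotation]:
    out: list[TelomereAnnotation] = []
    for sid, seq in scaffolds.scaffolds.items():
        out.extend(find_terminal_repeats(sid, seq, **kwargs))
    return out


@dataclass
class ScaffoldClass:
    """Per-scaffold telomere class plus genome-wide counts."""

    classes: dict[str, str]  # scaffold_id -> 'T2T' | 'single_end' | 'none'
    n_t2t: int
    n_single_end: int
    n_none: int


def classify_scaffolds(
    annotations: list[TelomereAnnotation], scaffolds: ScaffoldSet
) -> ScaffoldClass:
    """Classify scaffolds as T2T (both ends), single-end, or telomere-free."""
    ends: dict[str, set[str]] = {sid: set() for sid in scaffolds.ids()}
    for ann in annotations:
        if ann.scaffold_id not in ends:
            raise ValueError(f"annotation references unknown scaffold {ann.scaffold_id!r}")
        ends[ann.scaffold_id].add(ann.end)
    classes = {}
    for sid, e in ends.items():
        classes[sid] = "T2T" if len(e) == 2 else ("single_end" if len(e) == 1 else "none")
    counts = Counter(classes.values())
    return ScaffoldClass(
        classes=classes,
        n_t2t=counts.get("T2T", 0),
        n_single_end=counts.get("single_end", 0),
        n_none=counts.get("none", 0),
    )
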