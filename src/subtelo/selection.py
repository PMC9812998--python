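"""Codon-aware pairwise alignment and Nei–Gojobori (1986) Ka/Ks.

The estimator is the classic counting method: per-codon synonymous and
nonsynonymous site fractions, substitution counts averaged over all
mutational pathways between observed codons (pathways passing through stop
codons are excluded), proportions corrected with the Jukes–Cantor formula
d = −(3/4)·ln(1 − 4p/3). A two-sided Fisher's exact test on the rounded
substitution table [[Sd, S−Sd], [Nd, N−Nd]] screens pairs whose substitution
counts are too small to support a Ka/Ks interpretation.

Conventions (fixed here because the method leaves them open):
  * site counting: mutations that create a stop codon count as nonsynonymous,
    so S + N = 3 × n_codons exactly;
  * multi-hit codons: Sd/Nd averaged over all orderings of the observed
    differences whose intermediate codons are not stops; if every ordering is
    blocked, all orderings are used as a fallback;
  * the standard nuclear genetic code only; internal stops abort the pair.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .duplication import fisher_exact

log = logging.getLogger("subtelo")

# ---------------------------------------------------------------------------
# Genetic code tables (standard code)
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = "ACGT"

CODON_TO_AA: dict[str, str] = {}
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            _c = _b1 + _b2 + _b3
            CODON_TO_AA[_c] = "*" if _c in STOP_CODONS else _TABLE.forward_table[_c]


def _single_nt_neighbors(codon: str) -> list[str]:
    out = []
    for i in range(3):
        for b in BASES:
            if b != codon[i]:
                out.append(codon[:i] + b + codon[i + 1:])
    return out


# synonymous / nonsynonymous single-nucleotide neighbours, stops excluded
SYN_NEIGHBORS: dict[str, list[str]] = {}
NONSYN_NEIGHBORS: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    if _aa == "*":
        continue
    syn, non = [], []
    for _n in _single_nt_neighbors(_c):
        if _n in STOP_CODONS:
            continue
        (syn if CODON_TO_AA[_n] == _aa else non).append(_n)
    SYN_NEIGHBORS[_c] = syn
    NONSYN_NEIGHBORS[_c] = non


@functools.lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one codon.

    Each of the 9 single-nucleotide changes contributes 1/3 of a site;
    changes into stop codons are nonsynonymous, so the counts sum to 3.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@functools.lru_cache(maxsize=None)
def codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 (Sd, Nd) between two codons, averaged over mutational pathways.

    All orderings of the observed per-position differences are enumerated;
    orderings whose intermediate codons are stops are excluded. Each step is
    scored synonymous iff it preserves the amino acid.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[float, float]]:
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != codon_b and not allow_stops:
                return None
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order, False) for order in itertools.permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:  # every ordering passes a stop; score them anyway
        valid = [walk(order, True) for order in itertools.permutations(diff)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-free codon columns shared by two coding sequences."""

    gene_a: str
    gene_b: str
    codons: list[tuple[str, str]]

    @property
    def n_codons(self) -> int:
        return len(self.codons)


def _check_cds(cds: str, name: str) -> None:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length of {name} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i} of {name}")


def _translate_codons(cds: str) -> str:
    aas = []
    for i in range(0, len(cds), 3):
        c = cds[i:i + 3]
        aas.append(CODON_TO_AA[c])
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


_protein_aligner: Optional[Align.PairwiseAligner] = None


def align_proteins(protein_a: str, protein_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine gaps) as two gapped strings."""
    global _protein_aligner
    if _protein_aligner is None:
        _protein_aligner = Align.PairwiseAligner()
        _protein_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _protein_aligner.mode = "global"
        _protein_aligner.open_gap_score = -10.0
        _protein_aligner.extend_gap_score = -0.5
    aln = _protein_aligner.align(protein_a, protein_b)[0]
    return str(aln[0]), str(aln[1])


def backtranslate_alignment(
    protein_alignment: tuple[str, str],
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Map a gapped protein alignment back onto its source codons.

    Columns with a gap in either protein are dropped; the remaining codon
    columns are returned in order. The proteins must be exact translations of
    the CDSs (terminal stop allowed) or an error naming the first offending
    position is raised.
    """
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows differ in length")
    _check_cds(cds_a, gene_a)
    _check_cds(cds_b, gene_b)
    prot_a = _translate_codons(cds_a)
    prot_b = _translate_codons(cds_b)
    if row_a.replace("-", "") != prot_a:
        raise ValueError(f"protein of {gene_a} does not match translation of its CDS")
    if row_b.replace("-", "") != prot_b:
        raise ValueError(f"protein of {gene_b} does not match translation of its CDS")

    codons: list[tuple[str, str]] = []
    ia = ib = 0
    for col, (aa, ab) in enumerate(zip(row_a, row_b)):
        ca = cds_a[3 * ia:3 * ia + 3] if aa != "-" else None
        cb = cds_b[3 * ib:3 * ib + 3] if ab != "-" else None
        if ca is not None and CODON_TO_AA[ca] != aa:
            raise ValueError(
                f"translation mismatch for {gene_a} at alignment column {col}: "
                f"codon {ca} is {CODON_TO_AA[ca]}, alignment says {aa}"
            )
        if cb is not None and CODON_TO_AA[cb] != ab:
            raise ValueError(
                f"translation mismatch for {gene_b} at alignment column {col}: "
                f"codon {cb} is {CODON_TO_AA[cb]}, alignment says {ab}"
            )
        if ca is not None and cb is not None:
            codons.append((ca, cb))
        if aa != "-":
            ia += 1
        if ab != "-":
            ib += 1
    return CodonAlignment(gene_a, gene_b, codons)


# ---------------------------------------------------------------------------
# Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: Optional[float]  # Jukes–Cantor corrected dS; None if undefined
    ka: Optional[float]
    ratio: Optional[float]  # None when Ks = 0 or a correction is undefined
    fisher_p: float
    flags: list[str] = field(default_factory=list)


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks on a codon alignment, with the exact-test p-value."""
    if aln.n_codons == 0:
        raise ValueError("empty codon alignment")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in aln.codons:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = codon_path_counts(ca, cb)
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    flags: list[str] = []
    ks = _jc_correct(pS)
    ka = _jc_correct(pN)
    if ks is None:
        flags.append("ks_correction_undefined")
    if ka is None:
        flags.append("ka_correction_undefined")
    ratio: Optional[float] = None
    if ks is not None and ka is not None:
        if ks == 0.0:
            flags.append("ks_zero")
        else:
            ratio = ka / ks
    p = kaks_exact_test(S, N, sd, nd)
    return KaKsResult(
        aln.gene_a, aln.gene_b, aln.n_codons, S, N, sd, nd, pS, pN, ks, ka, ratio, p, flags
    )


def kaks_exact_test(S: float, N: float, Sd: float, Nd: float) -> float:
    """Two-sided Fisher's exact test on the rounded substitution table."""
    S_i, N_i = round(S), round(N)
    Sd_i, Nd_i = round(Sd), round(Nd)
    Sd_i = min(Sd_i, S_i)
    Nd_i = min(Nd_i, N_i)
    return fisher_exact([[Sd_i, S_i - Sd_i], [Nd_i, N_i - Nd_i]])


def kaks_for_cds_pair(
    cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b"
) -> KaKsResult:
    """Convenience route: align proteins, back-translate, run NG86."""
    pa, pb = _translate_codons(cds_a), _translate_codons(cds_b)
    aln = backtranslate_alignment(align_proteins(pa, pb), cds_a, cds_b, gene_a, gene_b)
    return kaks_ng86(aln)


# ---------------------------------------------------------------------------
# Selection summaries
# ---------------------------------------------------------------------------

@dataclass
class SelectionSummary:
    pair_class: str
    n_pairs: int
    n_defined: int
    mean_ratio: Optional[float]
    n_unreliable: int  # pairs whose exact test has p > alpha
    n_undefined: int  # Ks = 0 or correction undefined


def summarize_selection(
    results: Sequence[KaKsResult],
    class_labels: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, SelectionSummary]:
    """Per-class mean Ka/Ks over pairs with a defined ratio.

    Pairs with Ks = 0 (or an undefined distance correction) are excluded from
    the mean and counted separately; pairs whose exact test does not reach
    ``alpha`` are flagged unreliable but still averaged.
    """
    if not results:
        raise ValueError("no Ka/Ks results to summarize")
    if len(results) != len(class_labels):
        raise ValueError("results and class labels differ in length")
    out: dict[str, SelectionSummary] = {}
    for cls in dict.fromkeys(class_labels):
        rs = [r for r, c in zip(results, class_labels) if c == cls]
        defined = [r.ratio for r in rs if r.ratio is not None]
        mean = sum(defined) / len(defined) if defined else None
        if mean is None:
            log.warning("all Ka/Ks ratios undefined in class %r", cls)
        out[cls] = SelectionSummary(
            pair_class=cls,
            n_pairs=len(rs),
            n_defined=len(defined),
            mean_ratio=mean,
            n_unreliable=sum(1 for r in rs if r.fisher_p > alpha),
            n_undefined=len(rs) - len(defined),
        )
    return out
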