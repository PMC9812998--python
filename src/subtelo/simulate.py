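"""Synthetic genomes with planted truth for every pipeline stage.

The generator emulates the genome architecture the pipeline is built for:
compact chromosomes with terminal telomeric tandem arrays, 20–30 kbp
subtelomeric blocks shared across chromosome ends at a controlled
per-site divergence, duplicate gene families placed subtelomerically or
internally, codon sequences with controlled synonymous/nonsynonymous
divergence, Dollo-consistent presence/absence matrices, and transcripts
spanning several adjacent same-strand genes. Every planted object is
recorded in a TruthSet with resolvable coordinates in the emitted files.

Substitution-only model: no indels, no repeat families beyond the telomeric
arrays, no read-level noise. All randomness flows from a single integer seed
through per-object substreams keyed by stable string tags, so outputs are
byte-identical for a fixed config and insertion-order independent.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    PresenceAbsenceMatrix,
    ScaffoldSet,
    SpeciesTree,
    TranscriptAlignment,
    reverse_complement,
    write_bed12,
    write_fasta,
    write_gff3,
)
from .selection import NONSYN_NEIGHBORS, STOP_CODONS, SYN_NEIGHBORS

log = logging.getLogger("subtelo")

BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(SYN_NEIGHBORS)  # all 61 sense codons


def substream(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-object random stream keyed by a string tag."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    )


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random coding sequence: ATG start, sense-codon body, TAA stop."""
    body = rng.choice(_NONSTOP_CODONS, size=max(n_codons - 2, 0))
    return "ATG" + "".join(body) + "TAA"


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.where(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def mutate_cds(
    cds: str,
    syn_rate: float,
    nonsyn_rate: float,
    seed: Union[int, np.random.Generator],
) -> str:
    """Per-codon controlled mutation of a coding sequence.

    Each sense codon independently receives a synonymous substitution with
    probability ``syn_rate`` (drawn only from synonymous single-nucleotide
    alternatives; codons with none are skipped and logged) and a
    nonsynonymous substitution with probability ``nonsyn_rate`` (drawn only
    from nonsynonymous alternatives). Stop codons never arise and are never
    touched.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons[:-1]):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i}")
    out = []
    n_skipped = 0
    for codon in codons:
        if codon in STOP_CODONS:
            out.append(codon)
            continue
        if rng.random() < syn_rate:
            alts = SYN_NEIGHBORS[codon]
            if alts:
                codon = alts[rng.integers(0, len(alts))]
            else:
                n_skipped += 1
        if rng.random() < nonsyn_rate:
            alts = NONSYN_NEIGHBORS[codon]
            if alts:
                codon = alts[rng.integers(0, len(alts))]
        out.append(codon)
    if n_skipped:
        log.debug("mutate_cds: %d codons had no synonymous alternative", n_skipped)
    return "".join(out)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class DuplicateFamilySpec:
    copies: int
    placement: str  # 'subtelomeric' | 'internal'
    divergence: float  # per-codon nonsynonymous (and synonymous) rate per copy

    def __post_init__(self) -> None:
        if self.placement not in ("subtelomeric", "internal"):
            raise ValueError(f"bad placement {self.placement!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults realize a compact 10-chromosome alga-like genome: telomeres at
    both ends, a 25 kbp subtelomeric block shared by all 20 ends at 5%
    per-site divergence, one 5-copy subtelomeric and one 4-copy internal
    duplicate family, and 20 background genes per chromosome.
    """

    seed: int = 0
    n_chromosomes: int = 10
    chromosome_length: int = 120_000
    telomere_motif: str = "TTTAGGGC"  # configurable 8-mer stand-in, not a real motif
    telomere_copies: int = 50
    subtelomere_block_length: int = 25_000
    n_ends_sharing_block: int = 20
    block_divergence: float = 0.05
    gene_length_range: tuple[int, int] = (300, 900)  # nt, rounded to codons
    n_background_genes: int = 200
    duplicate_families: list[DuplicateFamilySpec] = field(
        default_factory=lambda: [
            DuplicateFamilySpec(5, "subtelomeric", 0.02),
            DuplicateFamilySpec(4, "internal", 0.02),
        ]
    )
    kaks_regimes: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.15, 0.02), (0.02, 0.15)]  # (syn, nonsyn)
    )
    kaks_n_pairs: int = 200
    kaks_n_codons: int = 480
    dollo_newick: str = "(((((A,B),(C,D)),((E,F),(G,H))),X),Y);"
    dollo_gain_leaves: tuple[str, ...] = ("A", "H")
    dollo_loss_prob: float = 0.2
    dollo_n_families: int = 200
    polycistron_n_transcripts: int = 8
    polycistron_genes_per_transcript: int = 2

    def __post_init__(self) -> None:
        if len(self.telomere_motif) < 4:
            raise ValueError("telomere motif must be at least 4 bp")
        if not 0 <= self.block_divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        tel = len(self.telomere_motif) * self.telomere_copies
        if 2 * (tel + self.subtelomere_block_length) > self.chromosome_length:
            raise ValueError(
                "telomeres plus subtelomeric blocks exceed the chromosome length"
            )
        if self.n_ends_sharing_block > 2 * self.n_chromosomes:
            raise ValueError("more sharing ends than chromosome ends")

    @property
    def telomere_length(self) -> int:
        return len(self.telomere_motif) * self.telomere_copies


End = tuple[str, str]


@dataclass
class FamilyTruth:
    family_id: str
    placement: str
    gene_ids: list[str]


@dataclass
class TruthSet:
    """Planted ground truth for a generated genome."""

    telomere_ends: list[End] = field(default_factory=list)
    telomere_spans: dict[End, tuple[int, int]] = field(default_factory=dict)
    subtelomere_intervals: dict[End, tuple[int, int]] = field(default_factory=dict)
    subtelomeric_genes: set[str] = field(default_factory=set)
    families: list[FamilyTruth] = field(default_factory=list)
    transcripts: list[TranscriptAlignment] = field(default_factory=list)
    polycistronic_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def duplicated_genes(self) -> set[str]:
        return {g for f in self.families for g in f.gene_ids}

    @property
    def duplicate_pairs(self) -> list[tuple[str, str, str]]:
        out = []
        for f in self.families:
            ids = sorted(f.gene_ids)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    out.append((a, b, f.placement))
        return out

    def stgd_ratio(self) -> Optional[float]:
        dup = self.duplicated_genes
        if not dup:
            return None
        return 100.0 * len(dup & self.subtelomeric_genes) / len(dup)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _gene_codons(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.gene_length_range
    return int(rng.integers(lo // 3, hi // 3 + 1))


def generate_genome(
    config: SimulationConfig,
) -> tuple[ScaffoldSet, list[GeneModel], TruthSet]:
    """Build the synthetic genome, its gene models, and the planted truth.

    Chromosome layout (mirrored on the right end; offsets relative to the
    inner edge of each telomere): 200 bp pad, a 1.2 kbp zone holding one
    end-specific single-copy gene, a 1 kbp slot where subtelomeric duplicate
    family copies are planted on selected ends, then the shared block
    sequence mutated per end at the configured divergence. The interior
    carries internal duplicate-family copies and background genes.
    """
    cfg = config
    seed = cfg.seed
    tel_len = cfg.telomere_length
    block = cfg.subtelomere_block_length
    L = cfg.chromosome_length
    if block < 3000:
        raise ValueError("subtelomere block must be at least 3 kbp for the layout")

    scaffold_ids = [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    ends: list[End] = [(sid, e) for sid in scaffold_ids for e in ("left", "right")]
    sharing = set(ends[:cfg.n_ends_sharing_block])

    telomere = cfg.telomere_motif * cfg.telomere_copies
    master_shared = random_dna(block - 2400, substream(seed, "master_shared"))
    master_famzone = random_dna(1000, substream(seed, "master_famzone"))

    # duplicate families: seed CDS + per-copy mutation, assigned to slots
    sub_specs = [f for f in cfg.duplicate_families if f.placement == "subtelomeric"]
    int_specs = [f for f in cfg.duplicate_families if f.placement == "internal"]
    fam_truth: list[FamilyTruth] = []
    sub_copy_at_end: dict[End, tuple[str, str]] = {}  # end -> (gene_id, cds)
    int_copy_at_chr: dict[str, tuple[str, str]] = {}

    shared_ends = [e for e in ends if e in sharing]
    end_cursor = 0
    for fi, spec in enumerate(sub_specs):
        fid = f"famS{fi + 1}"
        n_cod = min(_gene_codons(cfg, substream(seed, f"{fid}_len")), 1000 // 3)
        seed_cds = random_cds(n_cod, substream(seed, f"{fid}_seed"))
        ids = []
        for ci in range(spec.copies):
            if end_cursor >= len(shared_ends):
                raise ValueError("not enough shared ends for subtelomeric families")
            end = shared_ends[end_cursor]
            end_cursor += 1
            gid = f"{fid}_c{ci + 1}"
            cds = mutate_cds(
                seed_cds, spec.divergence, spec.divergence,
                substream(seed, f"{fid}_copy{ci}"),
            )
            sub_copy_at_end[end] = (gid, cds)
            ids.append(gid)
        fam_truth.append(FamilyTruth(fid, "subtelomeric", ids))

    chr_cursor = 0
    for fi, spec in enumerate(int_specs):
        fid = f"famI{fi + 1}"
        n_cod = min(_gene_codons(cfg, substream(seed, f"{fid}_len")), 400)
        seed_cds = random_cds(n_cod, substream(seed, f"{fid}_seed"))
        ids = []
        for ci in range(spec.copies):
            if chr_cursor >= len(scaffold_ids):
                raise ValueError("not enough chromosomes for internal families")
            sid = scaffold_ids[chr_cursor]
            chr_cursor += 1
            gid = f"{fid}_c{ci + 1}"
            cds = mutate_cds(
                seed_cds, spec.divergence, spec.divergence,
                substream(seed, f"{fid}_copy{ci}"),
            )
            int_copy_at_chr[sid] = (gid, cds)
            ids.append(gid)
        fam_truth.append(FamilyTruth(fid, "internal", ids))

    truth = TruthSet(telomere_ends=list(ends), families=fam_truth)
    scaffolds: dict[str, str] = {}
    gene_specs: list[tuple[str, str, str, list[tuple[int, int]]]] = []
    n_bg_per_chr = cfg.n_background_genes // cfg.n_chromosomes

    def build_block(end: End) -> tuple[str, list[tuple[str, str, int, int]]]:
        """One subtelomeric block in genomic order.

        Zones at rel offsets from the telomere's inner edge: 0–200 pad,
        200–1400 end-specific gene zone (CDS at rel 300), 1400–2400 family
        slot, 2400–block shared sequence. For a right end the zone order is
        mirrored genomically but rel offsets keep their terminus-anchored
        meaning. Genes returned as (id, strand, offset_in_block, cds_len)
        with offsets measured from the block's genomic start.
        """
        sid, side = end
        rng = substream(seed, f"block_{sid}_{side}")
        pad = random_dna(200, rng)
        uid = f"{sid}_u{'L' if side == 'left' else 'R'}"
        u_cds = random_cds(min(_gene_codons(cfg, rng), 366), rng)
        if end in sharing:
            fz_base = mutate_sequence(master_famzone, cfg.block_divergence, rng)
            rest = mutate_sequence(master_shared, cfg.block_divergence, rng)
        else:
            fz_base = random_dna(1000, rng)
            rest = random_dna(block - 2400, rng)
        fam = sub_copy_at_end.get(end)
        if side == "left":
            uz = random_dna(100, rng) + u_cds + random_dna(1100 - len(u_cds), rng)
            fz = (fam[1] + fz_base[len(fam[1]):]) if fam else fz_base
            seq = pad + uz + fz + rest
            genes = [(uid, "+", 300, len(u_cds))]
            if fam:
                genes.append((fam[0], "+", 1400, len(fam[1])))
        else:
            uz = random_dna(1100 - len(u_cds), rng) + u_cds + random_dna(100, rng)
            fz = (fz_base[:1000 - len(fam[1])] + fam[1]) if fam else fz_base
            seq = rest + fz + uz + pad
            # offsets from the block's genomic start (= interior side)
            genes = [(uid, "+", block - 300 - len(u_cds), len(u_cds))]
            if fam:
                genes.append((fam[0], "+", block - 1400 - len(fam[1]), len(fam[1])))
        return seq, genes

    poly_chrs = min(cfg.polycistron_n_transcripts, cfg.n_chromosomes)
    k_poly = cfg.polycistron_genes_per_transcript

    for ci, sid in enumerate(scaffold_ids):
        rng = substream(seed, f"interior_{sid}")
        left_seq, left_genes = build_block((sid, "left"))
        right_seq, right_genes = build_block((sid, "right"))
        b0_left = tel_len
        b0_right = L - tel_len - block

        pieces: list[str] = [telomere, left_seq]
        pos = b0_left + block
        interior_genes: list[tuple[str, str, int, int]] = []  # id, strand, start, len

        # background genes
        bg_ids: list[tuple[str, str, int, int]] = []
        for j in range(n_bg_per_chr):
            gap = int(rng.integers(100, 300))
            cds = random_cds(_gene_codons(cfg, rng), rng)
            strand = "+" if rng.random() < 0.5 else "-"
            # polycistron planting constrains strands (see below)
            if ci < poly_chrs and 5 <= j < 5 + k_poly:
                strand = "+"
            if ci == cfg.n_chromosomes - 1 and j in (5, 6):
                strand = "+" if j == 5 else "-"
            if ci == cfg.n_chromosomes - 2 and j in (10, 11):
                strand = "+"
            pieces.append(random_dna(gap, rng))
            start = pos + gap
            pieces.append(cds if strand == "+" else reverse_complement(cds))
            gid = f"{sid}_b{j:02d}"
            bg_ids.append((gid, strand, start, len(cds)))
            pos = start + len(cds)
        interior_genes.extend(bg_ids)

        # internal duplicate-family copy, planted at the chromosome midpoint
        # so it sits deep in the interior, far from any terminal window
        if sid in int_copy_at_chr:
            gid, cds = int_copy_at_chr[sid]
            mid = L // 2
            if pos > mid:
                raise ValueError("interior overflow before the midpoint slot")
            pieces.append(random_dna(mid - pos, rng))
            pieces.append(cds)
            interior_genes.append((gid, "+", mid, len(cds)))
            pos = mid + len(cds)

        fill = b0_right - pos
        if fill < 0:
            raise ValueError("interior overflow: genes do not fit the chromosome")
        pieces.append(random_dna(fill, rng))
        pieces.append(right_seq)
        pieces.append(telomere)
        seq = "".join(pieces)
        assert len(seq) == L
        scaffolds[sid] = seq

        for gid, strand, off, glen in left_genes:
            s = b0_left + off
            gene_specs.append((gid, sid, strand, [(s, s + glen)]))
        for gid, strand, off, glen in right_genes:
            s = b0_right + off
            gene_specs.append((gid, sid, strand, [(s, s + glen)]))
        for gid, strand, start, glen in interior_genes:
            gene_specs.append((gid, sid, strand, [(start, start + glen)]))

        # truth: telomeres and subtelomere intervals
        truth.telomere_spans[(sid, "left")] = (0, tel_len)
        truth.telomere_spans[(sid, "right")] = (L - tel_len, L)
        for side in ("left", "right"):
            if (sid, side) in sharing:
                truth.subtelomere_intervals[(sid, side)] = (
                    (tel_len, tel_len + block)
                    if side == "left"
                    else (L - tel_len - block, L - tel_len)
                )

        # transcripts: polycistronic positives and assorted negatives
        bg_by_j = {int(g[0].split("_b")[1]): g for g in bg_ids}
        if ci < poly_chrs:
            run = [bg_by_j[j] for j in range(5, 5 + k_poly)]
            tid = f"tx_poly_{sid}"
            s = run[0][2] - 20
            e = run[-1][2] + run[-1][3] + 20
            mid = run[0][2] + run[0][3] + 30  # split in the intergenic gap
            tx = TranscriptAlignment(tid, sid, "+", [(s, mid), (mid + 5, e)])
            truth.transcripts.append(tx)
            truth.polycistronic_map[tid] = [g[0] for g in run]
        if ci == cfg.n_chromosomes - 1 and 6 in bg_by_j:
            # opposite-strand spanning negative
            g5, g6 = bg_by_j[5], bg_by_j[6]
            truth.transcripts.append(
                TranscriptAlignment(
                    f"tx_anti_{sid}", sid, "+",
                    [(g5[2] - 10, g6[2] + g6[3] + 10)],
                )
            )
        if ci == cfg.n_chromosomes - 2 and 11 in bg_by_j:
            # partial-coverage negative
            g10, g11 = bg_by_j[10], bg_by_j[11]
            truth.transcripts.append(
                TranscriptAlignment(
                    f"tx_partial_{sid}", sid, "+",
                    [(g10[2] - 10, g11[2] + g11[3] - 30)],
                )
            )
        if ci == 0:  # monocistronic negative
            g0 = bg_by_j[0]
            truth.transcripts.append(
                TranscriptAlignment(f"tx_mono_{sid}", sid, g0[1], [(g0[2] - 10, g0[2] + g0[3] + 10)])
            )

    scaffold_set = ScaffoldSet(scaffolds)
    genes = [
        GeneModel.from_segments(gid, sid, strand, segs, scaffold_set)
        for gid, sid, strand, segs in gene_specs
    ]
    genes.sort(key=lambda g: (g.scaffold_id, g.start))

    # subtelomeric truth genes: those inside a planted shared block
    for g in genes:
        for (sid, _side), (lo, hi) in truth.subtelomere_intervals.items():
            if g.scaffold_id == sid and g.start >= lo and g.end <= hi:
                truth.subtelomeric_genes.add(g.gene_id)
    return scaffold_set, genes, truth


# ---------------------------------------------------------------------------
# Dollo presence/absence simulation
# ---------------------------------------------------------------------------

@dataclass
class DolloFamilyTruth:
    family_id: str
    gain_node: str
    planted_losses: set[str]
    present_leaves: set[str]
    consistent: bool  # planted pattern admits exactly the planted reconstruction


def simulate_dollo(
    tree: SpeciesTree,
    gain_node: str,
    loss_prob: float,
    n_families: int,
    seed: int,
) -> tuple[PresenceAbsenceMatrix, list[DolloFamilyTruth]]:
    """Single-gain families with independent per-branch losses.

    Each family is present at ``gain_node`` (a node label) and lost on every
    branch below it independently with probability ``loss_prob``; a lost
    subtree receives no deeper losses. Leaves outside the gain clade are
    absent. A family is flagged consistent when the presence pattern it
    leaves behind implies exactly the planted gain node and loss set under
    minimal single-gain reconstruction (a family lost from both children of
    a node, for instance, is not: the minimal reconstruction moves the loss
    up one branch).
    """
    gain = tree.node(gain_node)
    clade_leaves = tree.leaves_under(gain)
    taxa = tree.leaf_labels
    rows = []
    truths: list[DolloFamilyTruth] = []
    for fi in range(n_families):
        rng = substream(seed, f"dollo_{fi}")
        fid = f"fam{fi:04d}"
        losses: set[str] = set()
        present: set[str] = set()

        def descend(node) -> None:
            for child in tree.node(tree.label(node)).child_nodes():
                if rng.random() < loss_prob:
                    losses.add(tree.label(child))
                elif child.is_leaf():
                    present.add(child.taxon.label)
                else:
                    descend(child)

        if gain.is_leaf():
            present.add(gain.taxon.label)
        else:
            descend(gain)
        rows.append({t: int(t in present) for t in taxa})

        consistent = bool(present)
        if present:
            mrca = tree.mrca(present)
            canonical: set[str] = set()

            def canon(node) -> None:
                for child in node.child_nodes():
                    if tree.leaves_under(child) & present:
                        canon(child)
                    else:
                        canonical.add(tree.label(child))

            canon(mrca)
            consistent = tree.label(mrca) == gain_node and canonical == losses
        truths.append(DolloFamilyTruth(fid, gain_node, losses, present, consistent))
    matrix = PresenceAbsenceMatrix(
        pd.DataFrame(rows, index=[t.family_id for t in truths])
    )
    return matrix, truths


# ---------------------------------------------------------------------------
# Ka/Ks regime pairs
# ---------------------------------------------------------------------------

@dataclass
class KaKsPairTruth:
    pair_id: str
    syn_rate: float
    nonsyn_rate: float
    cds_a: str
    cds_b: str

    @property
    def regime(self) -> str:
        return "positive" if self.nonsyn_rate > self.syn_rate else "purifying"


def simulate_kaks_pairs(
    regimes: Sequence[tuple[float, float]],
    n_pairs: int,
    n_codons: int,
    seed: int,
) -> list[KaKsPairTruth]:
    """CDS pairs diverged at controlled (synonymous, nonsynonymous) rates.

    For each regime, ``n_pairs`` ancestors are drawn and one mutated copy is
    made per ancestor; the (ancestor, copy) pair carries the regime label.
    """
    out: list[KaKsPairTruth] = []
    for ri, (syn, nonsyn) in enumerate(regimes):
        for pi in range(n_pairs):
            tag = f"kaks_r{ri}_p{pi}"
            rng = substream(seed, tag)
            anc = random_cds(n_codons, rng)
            der = mutate_cds(anc, syn, nonsyn, rng)
            out.append(KaKsPairTruth(tag, syn, nonsyn, anc, der))
    return out


# ---------------------------------------------------------------------------
# Synteny partner genome
# ---------------------------------------------------------------------------

def simulate_synteny_partner(
    genes_a: Sequence[GeneModel],
    collinear_frac: float,
    seed: int,
) -> tuple[list[GeneModel], list[tuple[str, str]], float]:
    """A rearranged partner gene order with a planted collinear fraction.

    Per scaffold, the first ``collinear_frac`` of genes keep their order in
    the partner (a collinear run); the remainder are shuffled globally and
    appended in scattered order, so they sit in no block. Returns partner
    gene models (coordinates synthesised on partner scaffolds), the 1:1
    homolog pairs, and the planted collinear fraction actually realised.
    """
    rng = substream(seed, "synteny_partner")
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in sorted(genes_a, key=lambda g: (g.scaffold_id, g.start)):
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    runs: dict[str, list[str]] = {}
    scrap: list[str] = []
    n_collinear = 0
    for sid, gs in by_scaffold.items():
        k = int(round(collinear_frac * len(gs)))
        runs[sid] = [g.gene_id for g in gs[:k]]
        n_collinear += k
        scrap.extend(g.gene_id for g in gs[k:])
    order = rng.permutation(len(scrap))
    scrap = [scrap[i] for i in order]
    # distribute scrap across partner scaffolds, appended after each run;
    # never onto the partner of the gene's own scaffold, so a scattered gene
    # cannot extend its origin run into accidental collinearity
    sids = sorted(runs)
    origin = {g.gene_id: g.scaffold_id for g in genes_a}
    buckets: dict[str, list[str]] = {sid: [] for sid in sids}
    for i, gid in enumerate(scrap):
        candidates = [s for s in sids if s != origin[gid]] or sids
        buckets[candidates[i % len(candidates)]].append(gid)

    genes_b: list[GeneModel] = []
    pairs: list[tuple[str, str]] = []
    for sid in sids:
        pos = 0
        for gid in runs[sid] + buckets[sid]:
            bid = f"{gid}__p"
            genes_b.append(
                GeneModel(bid, f"{sid}__p", "+", [(pos, pos + 100)])
            )
            pairs.append((gid, bid))
            pos += 300
    total = sum(len(v) for v in by_scaffold.values())
    return genes_b, pairs, 100.0 * n_collinear / total


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_genome_outputs(
    outdir: str | Path,
    scaffolds: ScaffoldSet,
    genes: Sequence[GeneModel],
    truth: TruthSet,
) -> dict[str, Path]:
    """Emit FASTA + GFF3 + protein/CDS FASTA + BED12 + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "proteins": outdir / "proteins.faa",
        "cds": outdir / "cds.fna",
        "transcripts": outdir / "transcripts.bed",
        "truth_telomeres": outdir / "truth_telomeres.tsv",
        "truth_subtelomeres": outdir / "truth_subtelomeres.tsv",
        "truth_families": outdir / "truth_families.tsv",
        "truth_polycistrons": outdir / "truth_polycistrons.tsv",
    }
    write_fasta(scaffolds, paths["genome"])
    write_gff3(list(genes), paths["gff"])
    write_fasta({g.gene_id: g.protein_sequence for g in genes}, paths["proteins"])
    write_fasta({g.gene_id: g.cds_sequence for g in genes}, paths["cds"])
    write_bed12(truth.transcripts, paths["transcripts"])
    pd.DataFrame(
        [
            {"scaffold": sid, "end": end, "start": s, "stop": e}
            for (sid, end), (s, e) in sorted(truth.telomere_spans.items())
        ]
    ).to_csv(paths["truth_telomeres"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"scaffold": sid, "end": end, "start": s, "stop": e}
            for (sid, end), (s, e) in sorted(truth.subtelomere_intervals.items())
        ]
    ).to_csv(paths["truth_subtelomeres"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"family": f.family_id, "placement": f.placement, "gene": g}
            for f in truth.families
            for g in f.gene_ids
        ]
    ).to_csv(paths["truth_families"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"transcript": tid, "gene": g}
            for tid, gs in sorted(truth.polycistronic_map.items())
            for g in gs
        ]
    ).to_csv(paths["truth_polycistrons"], sep="\t", index=False)
    return paths
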