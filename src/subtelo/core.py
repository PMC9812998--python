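"""Domain types and file I/O shared by all pipeline stages.

All internal coordinates are 0-based half-open; GFF3/BED conversions happen
only at the I/O boundary. Sequences are uppercase over the ACGTN alphabet —
other ambiguity codes are rejected at read time because the downstream codon
statistics assume a 4-letter alphabet.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("subtelo")

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard code, dropping a terminal stop."""
    prot = str(Seq(cds).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


# ---------------------------------------------------------------------------
# ScaffoldSet
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldSet:
    """Named nucleotide sequences; the coordinate frame for everything else."""

    scaffolds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise ValueError(f"empty sequence for scaffold {sid!r}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"scaffold {sid!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __contains__(self, sid: str) -> bool:
        return sid in self.scaffolds

    def __getitem__(self, sid: str) -> str:
        return self.scaffolds[sid]

    def ids(self) -> list[str]:
        return list(self.scaffolds)

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.scaffolds.items()}


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene: CDS segments on a scaffold plus derived sequences.

    ``cds_segments`` are 0-based half-open genomic intervals sorted by start;
    ``cds_sequence`` is the spliced, strand-corrected coding sequence and
    ``protein_sequence`` its standard-code translation without terminal stop.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_sequence: str = ""
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        self.cds_segments = segs

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent from first to last CDS base (half-open)."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    @property
    def complete(self) -> bool:
        return len(self.cds_sequence) % 3 == 0

    @classmethod
    def from_segments(
        cls,
        gene_id: str,
        scaffold_id: str,
        strand: str,
        segments: list[tuple[int, int]],
        scaffolds: ScaffoldSet,
    ) -> "GeneModel":
        seq = scaffolds[scaffold_id]
        for s, e in segments:
            if s < 0 or e > len(seq):
                raise ValueError(
                    f"CDS segment ({s},{e}) of {gene_id} outside scaffold "
                    f"{scaffold_id} (length {len(seq)})"
                )
        spliced = "".join(seq[s:e] for s, e in sorted(segments))
        if strand == "-":
            spliced = reverse_complement(spliced)
        prot = translate(spliced) if len(spliced) % 3 == 0 else ""
        return cls(gene_id, scaffold_id, strand, segments, spliced, prot)


# ---------------------------------------------------------------------------
# SpeciesTree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted species tree (binary or multifurcating) with addressable nodes.

    Thin wrapper over a dendropy Tree. Unlabelled internal nodes receive
    stable postorder labels ``n0, n1, ...`` so gains and losses can be
    reported on named branches.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels: list[str] = []
        i = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.annotations["st_label"] = node.taxon.label
            else:
                lab = node.label if node.label else f"n{i}"
                i += 1
                node.annotations["st_label"] = lab
            labels.append(node.annotations["st_label"].value)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels in species tree")
        self._by_label = {
            node.annotations["st_label"].value: node
            for node in tree.postorder_node_iter()
        }

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
        return cls(tree)

    def label(self, node: dendropy.Node) -> str:
        return node.annotations["st_label"].value

    def node(self, label: str) -> dendropy.Node:
        return self._by_label[label]

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def n_internal(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter() if not n.is_leaf())

    def mrca(self, leaf_labels: Iterable[str]) -> dendropy.Node:
        """Set-wise most recent common ancestor of the named leaves."""
        labels = set(leaf_labels)
        missing = labels - set(self.leaf_labels)
        if missing:
            raise KeyError(f"unknown leaves: {sorted(missing)}")
        if len(labels) == 1:
            return self.node(next(iter(labels)))
        node = self.node(next(iter(labels)))
        while True:
            under = {lf.taxon.label for lf in node.leaf_iter()}
            if labels <= under:
                return node
            node = node.parent_node

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}


# ---------------------------------------------------------------------------
# PresenceAbsenceMatrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceAbsenceMatrix:
    """Binary family × taxon matrix of gene-family presence calls."""

    data: pd.DataFrame  # index: family_id, columns: taxon_id, values {0,1}

    def __post_init__(self) -> None:
        vals = set(pd.unique(self.data.values.ravel()))
        if not vals <= {0, 1}:
            raise ValueError(f"presence/absence matrix must be binary, got {vals}")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def row(self, family_id: str) -> dict[str, int]:
        return self.data.loc[family_id].to_dict()

    def validate_against(self, tree: SpeciesTree) -> None:
        missing = set(self.taxa) - set(tree.leaf_labels)
        if missing:
            raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="family_id")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ScaffoldSet:
    """Read a FASTA file into a ScaffoldSet.

    Record ids are the first whitespace token of the header; sequences are
    case-folded to uppercase. Duplicate ids and empty records are errors.
    """
    scaffolds: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        scaffolds[rec.id] = seq
    return ScaffoldSet(scaffolds)


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read any FASTA (protein or nucleotide) as a plain id → sequence map.

    Same id/duplicate handling as ``read_fasta`` but without the genomic
    ACGTN alphabet restriction — use this for proteomes and CDS sets.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str] | ScaffoldSet, path: str | Path, width: int = 70) -> None:
    if isinstance(seqs, ScaffoldSet):
        seqs = seqs.scaffolds
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff3(path: str | Path, scaffolds: ScaffoldSet) -> list[GeneModel]:
    """Read gene models (gene/mRNA/CDS features) from a GFF3 file.

    File coordinates are 1-based inclusive and converted to internal 0-based
    half-open intervals; − strand CDS are spliced then reverse-complemented.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in scaffolds:
            raise ValueError(f"unknown scaffold id {gene.seqid!r} for gene {gene.id}")
        cds = sorted(
            db.children(gene.id, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds:
            continue
        segments = [(f.start - 1, f.end) for f in cds]
        genes.append(
            GeneModel.from_segments(gene.id, gene.seqid, gene.strand, segments, scaffolds)
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/CDS feature triples (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            base = f"{g.scaffold_id}\tsubtelo\t"
            tail = f"\t{g.strand}\t"
            fh.write(f"{base}gene\t{s + 1}\t{e}\t.{tail}.\tID={g.gene_id}\n")
            fh.write(
                f"{base}mRNA\t{s + 1}\t{e}\t.{tail}.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (cs, ce) in enumerate(g.cds_segments):
                fh.write(
                    f"{base}CDS\t{cs + 1}\t{ce}\t.{tail}0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                )


def read_newick(path: str | Path) -> SpeciesTree:
    text = Path(path).read_text()
    if text.count("(") != text.count(")"):
        raise ValueError(f"unbalanced parentheses in Newick file {path}")
    return SpeciesTree.from_newick(text)


@dataclass
class TranscriptAlignment:
    """A spliced transcript-to-genome alignment (exon blocks, one strand)."""

    transcript_id: str
    scaffold_id: str
    strand: str
    blocks: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        blocks = sorted(self.blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exon blocks in transcript {self.transcript_id}"
                )
        self.blocks = blocks


def read_bed12(path: str | Path) -> list[TranscriptAlignment]:
    """Read transcript alignments from a BED12 file (blocks → exon intervals)."""
    out: list[TranscriptAlignment] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line with {len(f)} fields in {path}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            out.append(TranscriptAlignment(name, chrom, strand, blocks))
    return out


def write_bed12(alignments: list[TranscriptAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            start = a.blocks[0][0]
            end = a.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in a.blocks)
            offsets = ",".join(str(s - start) for s, e in a.blocks)
            fh.write(
                f"{a.scaffold_id}\t{start}\t{end}\t{a.transcript_id}\t0\t{a.strand}"
                f"\t{start}\t{end}\t0\t{len(a.blocks)}\t{sizes}\t{offsets}\n"
            )
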