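# subtelo

Comparative-genomics toolkit for **subtelomere biology in compact genomes**:
detecting telomeric repeat arrays and the conserved telomere-proximal
(subtelomeric) regions of chromosome ends, quantifying **subtelomeric gene
duplication (STGD)**, and running the surrounding analyses — Ka/Ks selection
tests, Dollo-parsimony gain/loss mapping, collinear synteny blocks,
polycistronic-transcript calling and OD₇₅₀ growth rates.

The toolkit targets genomes like those of thermoacidophilic red algae
(Cyanidiophyceae): tens of small chromosomes whose ends carry short tandem
telomeric repeats followed by 20–30 kbp blocks that are conserved *across*
chromosome ends within a genome, and where duplicated gene families
(heavy-metal detoxification genes among them) preferentially accumulate.
It is aimed at researchers who have chromosome-level assemblies with CDS
annotations and want reproducible, scriptable answers to: where are the
telomeres and subtelomeres, which duplications are subtelomeric, and is the
association between duplication and subtelomeres statistically real?

## The core quantities

* **Telomere detection** — for each scaffold terminus, the tandem period
  p ∈ [4, 12] maximizing the matched array span under a 20% per-copy
  mismatch budget; reported as the lexicographically smallest
  rotation/strand of the consensus motif with fractional copy number.
  Scaffolds are classed T2T (both ends), single-end, or telomere-free.
* **Subtelomere delineation** — all terminal windows (50 kbp) of a genome
  aligned against each other (k-mer seeding, same-diagonal chaining,
  ungapped X-drop extension, both strands); per end, supporting blocks are
  merged (gap ≤ 2 kbp), anchored at the terminus and clipped to 30 kbp.
* **Recent duplications and the STGD ratio** — all-vs-all local protein
  alignment (BLOSUM62); a pair is a duplicate in grid cell (i, c) when
  identity ≥ i and *both* coverages ≥ c, over the canonical 5 × 5 grid
  70–90% in 5% steps; families are connected components. The STGD ratio is

      STGD% = 100 · |duplicated ∩ subtelomeric| / |duplicated|

  with a two-sided Fisher's exact test on the
  {subtelomeric, other} × {duplicated, other} table.
* **Ka/Ks (NG86)** — Nei–Gojobori counting on codon alignments
  (back-translated from BLOSUM62 protein alignments): pathway-averaged
  substitution counts (stop-passing pathways excluded), Jukes–Cantor
  correction d = −(3/4)·ln(1 − 4p/3), and a Fisher exact test on
  [[Sd, S−Sd], [Nd, N−Nd]] to flag pairs with too few substitutions.
* **Dollo parsimony** — one gain at the MRCA of the carrying taxa, losses on
  the maximal absent subtrees beneath it; per-branch gain/loss totals.
* **Collinearity** — MCScanX-style chains of homologous gene pairs
  (block ≥ 5 anchors, rank gap ≤ 25, same or inverted orientation) via
  longest-chain dynamic programming; per-genome collinear gene fractions.
* **Polycistrons** — a transcript is polycistronic when its exon-block
  union completely covers ≥ 2 same-strand gene (CDS) spans.
* **Growth rate** — μ = (ln OD₂ − ln OD₁)/(t₂ − t₁) per day from corrected
  (blank-subtracted) OD₇₅₀, with per-treatment mean ± SE.

A synthetic-genome generator plants all of these signals with known truth
(telomere arrays, shared subtelomeric blocks at controlled divergence,
duplicate families placed subtelomerically or internally, codon pairs with
controlled synonymous/nonsynonymous rates, Dollo presence/absence matrices,
polycistronic transcripts), so every stage is testable end-to-end without
external data.

## Worked example

Run the end-to-end demo on one seed (simulate → telomeres → subtelomeres →
STGD → Ka/Ks → Dollo → synteny → polycistrons):

```bash
subtelo demo --seed 1 --outdir demo_out
```

Output (abridged):

```
telomeric_ends_detected 20
subtelomere_regions_detected    20
stgd_ratio_detected     55.55555555555556
stgd_ratio_truth        55.55555555555556
stgd_fisher_p   0.0009776550433908938
kaks_sign_recovery_purifying_pct        100.0
kaks_sign_recovery_positive_pct 100.0
dollo_exact_recovery_pct        100.0
collinear_fraction_detected     60.0
polycistron_calls       8
```

Reading this: all 20 planted telomeric ends and all 20 shared 25 kbp
subtelomeric blocks (5% divergence) were recovered; the detected STGD ratio
equals the planted truth exactly (5 of the 9 duplicated genes — the 5-copy
subtelomeric family — are subtelomeric, 55.6%), and the Fisher test calls
the duplication–subtelomere association significant. Both selection regimes
(synonymous-dominated and nonsynonymous-dominated codon divergence) are
recovered with the correct Ka/Ks sign in 100% of 200 pairs each; Dollo
reconstruction matches every tree-consistent planted family; and the
partner genome with 60% of genes in planted collinear runs yields exactly a
60% collinear fraction.

Individual stages run as subcommands on your own files, e.g.:

```bash
subtelo telomeres --fasta genome.fasta --outdir out
subtelo subtelomeres --fasta genome.fasta --gff genes.gff3 --outdir out
subtelo stgd --proteins out/proteins.faa --subtel-genes out/subtelomere_genes.tsv
subtelo kaks --cds cds.fna --pairs pairs.tsv
subtelo dollo --tree species.nwk --matrix presence.tsv
subtelo growth --od od750.tsv
```

All thresholds live in one YAML config (`--config`); unknown keys are
rejected and the resolved configuration is written next to the outputs.

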