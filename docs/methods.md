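# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind each stage of the pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates, sequences, trees

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and BED are converted only at the I/O boundary, which removes an entire
class of off-by-one drift. Sequences are uppercase ACGTN; ambiguity codes
other than N are rejected at read time because the codon statistics assume
a 4-letter alphabet. Gene models are CDS-defined: the genomic "span" of a
gene is first-to-last coding base. Genes whose CDS length is not divisible
by 3 are retained for positional analyses but excluded from translation
and Ka/Ks, mirroring real annotation sets with partial models. Species
trees may be multifurcating; unlabelled internal nodes get stable
postorder labels (`n0`, `n1`, ...) so branches can be named in reports.

## Telomere detection

For each terminus, every candidate period p ∈ [4, 12] and array start
within 50 bp of the terminus is scored by greedy tandem extension: a copy
matches the terminal template if its Hamming distance is within
⌊0.2·p⌋. The candidate with the largest matched span wins; ties go to
the smaller period (so a hexamer array is not reported as its 12-mer
doubling) and then the smaller offset. Copy number is matched span divided
by period — fractional, since arrays rarely end on a motif boundary. The
reported motif is the per-column majority consensus canonicalized as the
lexicographically smallest rotation over both strands, making the report
invariant to rotation and strand. Defaults (window 3 kbp, ≥ 8 copies,
20% mismatch) reflect that telomeric arrays are terminal, short-period and
locally homogeneous; they are configurable because real motifs and array
lengths vary by lineage. The default simulated motif is an arbitrary 8-mer:
it deliberately does not pretend to be any real species' repeat.

## Subtelomere delineation

Terminal windows (default 50 kbp) of all telomere-bearing ends are compared
pairwise on both strands: exact 15-mer seeds (k-mers occurring > 10 times
per window are skipped, which silently drops the telomeric arrays
themselves), seeds clustered on shared diagonals (gap ≤ 400 bp), ungapped
X-drop extension (match +1, mismatch −3, drop 15), blocks kept at
≥ 500 bp and ≥ 70% identity. Same-scaffold window overlaps are excluded
as self-matches. The aligner assumes end divergence is substitution-
dominated; small indels appear as block splits that the downstream merge
bridges — it is not a general genome aligner, and 15-mer seeding loses
sensitivity beyond roughly 15–20% divergence (at 5% divergence the
expected seed survival per position is 0.95¹⁵ ≈ 0.46, ample).

Per end, block intervals are merged across partners (gap ≤ 2 kbp),
anchored at the terminus, and clipped to a 30 kbp maximum extent —
bracketing the 20–30 kbp conserved blocks such regions typically span,
with larger outliers reachable by raising `max_extent` (e.g. to 44 kbp) in
the config. `support` counts distinct partner ends; the default
`min_support` = 1 keeps any end corroborated by at least one other end.
Ends with a telomere but no conserved block can optionally emit a bare
region (telomere span + flank), since whether such ends count as
subtelomeres is a matter of definition; the default leaves them out.

Gene membership uses fractional span overlap (≥ 50% of the gene's span
inside the region), with a gene assigned to at most one region — larger
overlap wins, ties go to the closer terminus. Midpoint or any-overlap
rules would differ only for genes straddling a region edge.

## Duplicate detection and the STGD ratio

All-vs-all local protein alignment uses BLOSUM62 with affine gaps
(open −11, extend −1). Percent identity divides matches by alignment
columns *including* gap columns ('X' never matches), which is the common
aligner-report convention; coverage is the aligned span over each
sequence's length, and both query and subject coverage must pass a cell's
threshold. The canonical grid is 70–90% identity × 70–90% coverage in 5%
steps (25 cells); the headline report uses the most permissive cell
(70, 70) with the full grid emitted alongside. A cheap shared-5-mer
prefilter (≥ 3 shared k-mers) skips hopeless pairs; at ≥ 70% identity the
expected shared-k-mer count is far above the cutoff, so the prefilter does
not affect the grid range (it can be disabled). Families are connected
components over kept pairs — single linkage, the simplest reading of
"grouping duplicate pairs"; no reciprocal-best filtering.

The STGD ratio is 100 × (duplicated genes in subtelomeric regions) /
(duplicated genes). Association is tested with a two-sided Fisher's exact
test on the 2×2 location × duplication table; p is the total
hypergeometric mass of margin-consistent tables no more probable than the
observed one (ties within ~1e-7 relative tolerance), computed via
scipy and verified in the tests against exhaustive enumeration.
Degenerate margins return p = 1 by convention.

## Ka/Ks (NG86)

Codon alignments come from global BLOSUM62 protein alignments
back-translated onto the CDSs; columns with a gap in either protein are
dropped, and any translation mismatch aborts the pair with the offending
position named. Internal stops abort the pair (standard nuclear code only).

Counting follows Nei–Gojobori (1986). Two conventions the original method
leaves open are fixed as follows and enforced by the oracle tests:

* **Site counting.** Each of a codon's nine single-nucleotide changes
  contributes ⅓ site; changes creating a stop codon count as
  nonsynonymous. Consequence: S + N = 3 × n_codons exactly.
* **Multi-hit codons.** Sd/Nd are averaged over all orderings of the
  observed differences whose intermediates are not stops; if every
  ordering is blocked (rare), all orderings are used.

Proportions pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (flagged). Pairs with
Ks = 0 have no defined ratio; they are excluded from class means and
counted separately, because near-identical duplicates with a handful of
substitutions are a real and informative occurrence, not missing data.
A two-sided Fisher exact test on [[Sd, S−Sd], [Nd, N−Nd]] (counts rounded)
flags pairs whose substitution counts cannot support a selection call;
flagged pairs are still averaged but reported. NG86 was chosen over
ML estimators (GY94 etc.) because it is fully specifiable and
oracle-checkable by brute-force pathway enumeration; model-averaging
estimators are out of scope.

## Dollo gain/loss

Under Dollo parsimony each family arises once — on the branch to the MRCA
of its carriers — and is lost on the branches to the maximal carrier-free
subtrees beneath the gain. This loss set is provably minimal given the
single-gain constraint; the tests verify it against exhaustive
minimization over every rooted binary topology with ≤ 6 leaves and every
presence pattern. Families present in all taxa gain on the root branch
("ancestral" content, reported in a distinguished root bucket).
Singletons are annotated like any family, with a flag. Functional-category
summaries are a user-side join, not computed here.

## Collinearity

Anchors are homologous gene pairs; gene rank is the order along each
scaffold by start coordinate. Per scaffold pair and orientation, chains
are found by O(n²) longest-chain DP: ranks strictly increase in genome a
and increase (same) or decrease (inverted) in genome b, with at most 25
intervening genes between consecutive anchors on either side; blocks need
≥ 5 anchors. Chain score is the anchor count with ties broken toward
fewer rank gaps — anchor count is the auditable core of MCScanX-style
scoring without reproducing its full scheme. Chains are extracted
best-first and each anchor used once. Tandem partners (consecutive ranks)
are collapsed to the best-scoring pair per cluster before chaining, so an
array cannot inflate a block. The collinear fraction is the percent of a
genome's genes in ≥ 1 block, reported per genome and as the mean; a
multi-genome "shared collinear" set is the intersection of pairwise
covered sets, since any aggregation choice (per-genome, union,
intersection) gives slightly different numbers and all three are exposed.

## Polycistrons

A transcript is polycistronic when the union of its exon blocks covers
every base of ≥ 2 same-strand gene CDS spans. Coverage is measured
against the CDS span because gene models here are CDS-defined (a full
gene-span mode would differ only with annotated UTRs). Only the covering
union matters — spliced alignments are fine — and calls are invariant to
splitting or merging abutting blocks. The gene fraction divides by all
annotated genes; restricting to expressed genes would raise it.

## Growth rates

μ = (ln OD₂ − ln OD₁)/(t₂ − t₁) per day on corrected (blank-subtracted)
OD₇₅₀. Blank subtraction happens at ingest; a blank exceeding a dilute
sample yields a clamped (10⁻⁶) and flagged value rather than a silent
drop. Summaries are per-treatment mean ± SE (SD/√n); single replicates
get a missing SE and a flag. μ is scale- and time-shift-invariant, which
the property tests exercise.

## Synthetic data: what it emulates, and what it does not

Default study conditions: 10 chromosomes of 120 kbp; telomeres of 50 × an
8-mer at both ends; a 25 kbp block shared by all 20 ends at 5% per-site
divergence; per end, a 1.2 kbp zone with one end-specific single-copy gene
and a 1 kbp slot where subtelomeric family copies are planted; one 5-copy
subtelomeric and one 4-copy internal duplicate family (per-copy codon
mutation rate 0.02 syn + 0.02 nonsyn), the internal family at chromosome
midpoints so it stays clear of any terminal window; 200 background genes
(~20 per chromosome, 300–900 nt); 8 two-gene polycistronic transcripts
plus mono-cistronic, partial-coverage and antisense negatives. These sizes
keep a full demo fast while leaving every effect (e.g. the planted STGD
ratio of 5/9 ≈ 55.6%) far from its detection threshold. Ka/Ks regimes are
(syn, nonsyn) = (0.15, 0.02) and (0.02, 0.15) over 480 codons — about the
length of the metal-detoxification genes such analyses target — with 200
pairs per regime, where the expected Ka/Ks of ≈ 0.04 and ≈ 2.5 make sign
recovery a sharp but fair test. Dollo simulation places a gain on a named
node and loses each branch beneath independently (p = 0.2, 200 families
on a 10-taxon tree); a lost subtree receives no deeper events. Families
whose pattern no longer implies the planted reconstruction (e.g. both
children of a node lost, so the minimal loss moves up one branch) are
flagged inconsistent, and exact-recovery checks apply to consistent
families only — for the rest, "recovery" is undefined, not failed.

Determinism: every random draw comes from a per-object substream keyed by
(seed, stable string tag), so outputs are byte-identical for a fixed
config and independent of insertion order.

Deliberate non-realism, and hence what passing tests do *not* show: no
indels (real subtelomeres rearrange, so block boundaries in real data are
fuzzier than Jaccard ≥ 0.8 here suggests), no transposable elements or
segmental repeats beyond the telomeric arrays (real end windows contain
confounding repeats that the > 10-hit k-mer skip only partly emulates),
uniform base composition, no annotation errors, no read-level noise, and
transcripts are given as clean alignments rather than mapped reads.
Accession-scale inputs also bring scale: tens of Mbp and 5–7 k proteins,
where the all-vs-all and end-alignment stages take correspondingly longer.

## Problem sizes used by the checks

The default test suite and the acceptance script run: the 10-chromosome
demo genome above; 100 random 2×2 tables (N ≤ 40) against the Fisher
enumeration oracle; 50 random 100-codon pairs against the NG86 pathway
oracle; all 1,069 rooted binary topologies with 2–6 leaves × all presence
patterns (63,039 cases) against the Dollo minimization oracle; and 30
random ≤ 15-anchor instances (both orientations) against the brute-force
chain oracle. These sizes were chosen as the smallest that exercise every
code path and tie-break.
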