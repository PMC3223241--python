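# Methods

`baculoannot` re-implements, as one reusable pipeline, the analyses that
underlie the genome characterisation of a small circular dsDNA insect
virus (a granulovirus): ORF calling under explicit selection rules,
promoter-motif association, homology-based gene classification,
dot-plot and gene-order comparison, and concatenated-gene
maximum-parsimony phylogenetics.  This note records the models,
conventions, parameter choices and their limits.

## Coordinates and anchoring

All public coordinates are 1-based inclusive, matching GenBank and GFF3.
An ORF stores `start` = first nucleotide of the start codon and `end` =
last nucleotide of the stop codon on the forward axis; on the reverse
strand transcription runs toward decreasing coordinates.  Features may
wrap the origin of a circular genome; a wrap shows up as the coordinate
inversion (`end < start` on the forward strand) plus an explicit flag,
and is written to GFF3 as a two-part feature sharing one ID and to
GenBank as a `join` across the origin.

Genomes of this family are conventionally numbered from the first
nucleotide of the start codon of the major occlusion-body protein gene
(granulin), in its direction of transcription.  `anchor_to_gene` applies
exactly this convention: rotate, and reverse-complement first if the
gene lies on the reverse strand.  Anchoring is idempotent, and rotation
or reflection of the input never changes lengths, base composition,
per-ORF lengths, or translations (tested properties).

## ORF calling

A candidate ORF is maximal: it begins at the first ATG after the
previous in-frame stop and runs through the next in-frame stop, in any
of the six frames, crossing the origin on circular genomes.  Two
conventions matter:

* Length counts the stop codon.  The classical "50 or more codons" rule
  is therefore ≥150 nt including the stop, i.e. a protein of ≥49 aa.
  `min_codons` defaults to 50.
* On a circular genome a reading frame that never meets a stop is
  capped at one genome length; such frames yield no ORF.

Enumeration is checked exactly against a brute-force scanner that tests
every position of every frame independently (100 seeded random circular
sequences up to 10 kb in the acceptance suite).

Selection is greedy longest-first: a candidate is admitted iff it
overlaps every already admitted ORF by at most `max_overlap_bp`
(default 47 bp — i.e. less than 16 codons, the conventional boundary
between "minimal" and notable overlaps in genomes of this family), or
it carries a homology-rescue flag supplied by the orthology stage.
Ties break by smaller start, then forward strand.  The genome summary
reports A+T percent (half-up, 1 decimal), strand split, the
adjacent-overlap table with circular adjacency (last ORF adjacent to
first), the count of minimally overlapping adjacent pairs (1–47 bp),
and the coding fraction under both definitions in use — Σ ORF length /
genome length and union-of-footprints / genome length — because
published coding percentages rarely state which one they are.

## Promoter scan

Baculovirus transcription signals are modelled the conventional way:
late = `DTAAG` (IUPAC, D = A/G/T); early = a TATA box (`TATAA`) with a
`CAGT` initiator starting 20–40 nt downstream of the TATA start.  Both
are sought on the ORF's coding strand within a window (default 120 nt)
immediately upstream of the ATG, wrapping the origin.  Upstream regions
overlapping a neighbouring ORF are still scanned; no masking.  Calls
are invariant under genome rotation, and widening the window can only
add hits (tested properties).  Motifs, window and spacing are
configurable (`key=pattern` files in the CLI); the defaults are the
field's standard definitions, and on real annotated genomes the
absolute number of ORFs with calls is inherently window- and
motif-definition-dependent.

## Homology

`align_local` is optimal Smith–Waterman with affine gaps, computed by
Biopython's `PairwiseAligner` configured so a gap of length L costs
`open + L·extend`, with BLOSUM62 / 11 / 1 (the BLASTP convention).
Percent identity is computed over aligned columns only.  The test suite
checks exact score agreement with an independent three-state DP on 200
random pairs.

Orthology is by reciprocal best hits: (a, b) is reported iff each is
the other's strictly unique best-scoring hit, with score ≥ 50 and ≥ 30
aligned columns (configurable).  There is no E-value machinery; score
thresholds keep the engine self-contained and deterministic.  The
ortholog table records, per focal gene and genome, the ortholog's name,
its rank along its own genome, and its strand relative to the focal
gene.  Gene classes over a labelled panel follow set definitions:
`core` = present in every panel genome; `group-specific` = present in
all genomes of exactly one group and no others; `unique` = focal
genome only; otherwise `shared-subset`.  Published core/GV-specific/
shared/unique counts depend on the panel composition, so the package
asserts only the procedure, not any fixed split.

## Synteny and gene order

The dot plot is exact k-mer matching (default word size 8 nt) on both
strands — the desk equivalent of the matrix plots used to show
co-linearity between related genomes.  Gene-order analysis reduces each
genome to a signed vector of reference-gene indices (sign = relative
strand).  A conserved run is a maximal block of reference genes that
occurs contiguously, in the same signed order or globally reversed, in
every vector, after restricting all vectors to the shared gene subset
(genomes of different groups retain different homolog subsets, so
restriction comes first).  The breakpoint distance counts
orientation-aware adjacencies of one vector missing from the other; it
is symmetric, non-negative, and zero exactly for identical or globally
reversed restricted orders.  Vectors are treated as linear in anchored
order; the origin-spanning adjacency of the circular genome is not
counted, which can shift run boundaries by one at the anchor point.

## Phylogenetics

Per-gene protein families are aligned progressively: UPGMA guide tree
from pairwise 3-mer distances, profiles merged by global DP with
sum-of-pairs BLOSUM62 scores and a linear gap penalty of 8 per residue
(affine profiles buy little at the family sizes involved and complicate
determinism; with two sequences the procedure is plain
Needleman–Wunsch, which is how it is tested).  Alignments are
concatenated in canonical gene order into a partitioned supermatrix;
taxa missing a gene are padded with gaps; columns can optionally be
dropped above a gap fraction (default off, 0.5 when enabled).

Tree length is Fitch parsimony with gaps and ambiguous residues as
missing data (any state), vectorised over columns with 20-bit state
masks; the score is invariant under re-rooting and leaf permutation.
The search is stepwise addition under a seeded random taxon order
followed by nearest-neighbour-interchange hill climbing, best of 10
restarts, ties broken by canonical Newick string.  On 5–6 taxa the
search provably returns the exhaustive optimum in the test suite.
Bootstrap resamples columns with replacement (as per-column weights),
reruns a cheaper search (2 restarts) per replicate, and reports the
percentage of replicate best trees containing each focal bipartition.
Replicate counts: classical practice is 1,000; the test and acceptance
runs use 100, which is enough to separate ~100% clades from noise at
desk scale.  Everything is reproducible bit-for-bit under a fixed seed.

## Synthetic data

The genome simulator emulates the structure of the real study system —
circular, 80–180 kb, 54–68% A+T, 100–180 mostly non-overlapping ORFs of
≥150 nt on both strands, promoter motifs upstream of most genes.
Defaults are study-scale: 124 kb, A+T target 61%, 130 ORFs of 300–1302
nt (≈82% coding), 42% reverse strand, late/early planting rates
0.55/0.30, minimum intergenic spacer 60 nt.  Background is i.i.d. with
base probabilities solving the A+T target; coding regions draw codons
with composition-matched weights (start and stop codons shift the
realised genome A+T ≈1 point below target, which is why tests allow
±1.5).

Planted ORFs are strictly non-overlapping; `max_planted_overlap` other
than 0 is rejected, since overlapping planted coding regions would need
bases satisfying two reading frames at once.  After planting, a cleanup
pass makes the planted truth the unique answer of the annotation stage:
chance background ORFs that would survive greedy selection are broken
by writing stops (or breaking start codons) into bases outside planted
footprints, each write checked not to create a new start codon nearby
and committed so later writes cannot undo it.  A planted ORF shadowed
by a chance upstream in-frame ATG is freed by breaking the extension.
Rarely (≈1% of draws at study scale) a chance reading frame lies
entirely within a planted gene's footprint and cannot be broken; such
draws are rejected and the genome redrawn from a deterministically
derived sub-seed, keeping output a pure function of the configured
seed.

The panel simulator evolves protein families along a user-supplied
Newick tree (per-site substitution probability 1−exp(−rate·branch
length), optional short indels with tracked per-residue ancestry for
alignment-truth tests), applies configured inversions/transpositions to
each non-focal genome's gene order, and reassembles annotated genomes
from back-translated genes.  The first leaf in tree order is the
anchored focal genome and keeps the identity order.

What the simulations do not emulate: codon-usage bias beyond base
composition, repetitive gene families (bro-like repeats), homopolymer
or tandem-repeat tracts, promoter-motif avoidance in background
sequence, and rate heterogeneity across sites or lineages.  Passing on
synthetic data therefore demonstrates algorithmic correctness against
planted truth, not robustness to every property of real genomes.

## Reference records

The checks that reproduce published numbers for deposited genomes
(genome length, A+T, CDS counts, strand split, overlap table,
cross-check genomes) read GenBank flat files from
`tests/data/refseq/<accession>.gb`.  These records are a ~124–179 kb
download each and are not shipped; without them those tests fail with
an explanatory message, while all planted-truth checks run anywhere.

## Numerical conventions

Percentages printed in summaries are rounded half away from zero to one
decimal before any comparison.  All stochastic stages take explicit
seeds; derived seeds stay below 2³¹.  Degenerate inputs are defined,
not special-cased ad hoc: empty ORF sets give 0% coding and an empty
overlap table; a zero-variation supermatrix yields a warning and
arbitrary but reproducible bootstrap supports; single sequences pass
through alignment unchanged; trees with <4 taxa return the trivial
topology.
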