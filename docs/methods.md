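# Methods

## Overview

`arcgen` implements an alignment-free comparative-genomics chain for
bacterial genome collections: whole-proteome vectorization with
neighbour-joining (NJ) phylogenomics, greedy protein clustering with
core-genome extraction, fragment/k-mer average nucleotide identity
(ANI) with mean-normalised heat-map matrices, and marker-panel analysis
that calls diazotrophy from the minimal *nif* gene set and attributes
the cassette to a donor lineage. A synthetic-genome generator with full
ground truth makes every stage verifiable end to end.

## Spaced-word proteome vectors

Each protein is scanned with the binary mask `11011` (window length 5,
weight k = 4). A window contributes the word formed by its residues at
the mask's care positions, encoded base-20 with the amino acids in
alphabetical order (A=0 … Y=19). Windows never span protein boundaries.
Non-canonical residues (B, J, O, U, X, Z, `*`) — which real annotations
contain — invalidate a window only when they fall on a care position;
at a don't-care position they are ignored. The proteome is summarized
by the binary occurrence vector over the 20ᵏ = 160,000 word space
(presence/absence by default, making the representation order-free and
robust to proteome size; counts are available as a flag), then
projected to p = 1369 dimensions.

The projection is a seeded Gaussian random matrix: entries are drawn
from a single standard-normal stream (`numpy` PCG64, fixed row-major
fill) and scaled by 1/√p, the Johnson–Lindenstrauss norm-preserving
scaling. The triple (mask, p, seed; default seed 20210107) fully
determines every vector, bit for bit, and is recorded in all vector
outputs; distance computations refuse to mix vectors with different
parameters. Because the reference tool's projection matrix is not
public, these vectors are **not interchangeable** with vectors from any
other implementation — only internally consistent. The matrix
(160,000 × 1369 ≈ 1.75 GB dense) is never materialized; it is streamed
in row blocks and applied to batches of occurrence vectors.

Genome-genome distances are Euclidean, computed once on the condensed
form and mirrored so matrices are exactly symmetric. A k-means overview
(k-means++ from a seed, 50 restarts, best inertia) with coordinates
from exact SVD of the mean-centred vector matrix reproduces the usual
two-principal-component cluster plot.

## Greedy protein clustering

Similarity between proteins is the shared contiguous 3-mer fraction
normalized by the smaller k-mer set:
`s(a,b) = |K(a) ∩ K(b)| / min(|K(a)|, |K(b)|)`. Any sequence with at
least one k-mer scores exactly 1 against itself, which anchors the 0.7
threshold on a self-score scale; sequences shorter than k score 0
against everything and become singletons. The exact scoring function of
the reference clustering tool is unpublished; this min-normalized k-mer
score is this package's pinned stand-in, so absolute cluster counts on
real data are not expected to match other tools — only the clustering
semantics (threshold on a self-normalized score) carry over.

Clustering is a single greedy pass: proteins in descending length
(ties by genome id, then protein id — a content-based order, so results
do not depend on file order), each compared against cluster
*representatives* only (the founding protein). The best-scoring
representative wins if its score is ≥ 0.7 (inclusive), ties resolving
to the lowest cluster id; otherwise the protein founds a new cluster.
A shared-k-mer inverted index prefilters candidates; since a pair
sharing no k-mer scores 0, the prefilter provably cannot change the
result (and a test verifies equality against exhaustive comparison).

The presence matrix counts members per cluster per genome; row sums
equal cluster sizes, and the grand total equals the number of input
proteins (a conservation property under test).

## Core genome

A cluster is core when every genome has ≥ 1 member (paralogs allowed;
an optional single-copy filter requires exactly one). The core share of
sequences is the fraction of all cluster members that live in core
clusters. For core-genome phylogenies each genome contributes one
protein per core cluster — its longest member there, ties to the
smallest protein id — keeping core proteomes comparable when paralog
counts differ.

## Neighbour joining, Newick, tree comparison

Classical Saitou–Nei NJ: join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), with branch lengths from
the standard two-point formulas and a final trifurcation by the
three-point formulas. Two behaviours that textbook statements leave
open are pinned for reproducibility: exact ties in Q resolve to the
lexicographically smallest label pair (an internal node carries the
smallest leaf label of its subtree), and a negative branch length is
clamped to zero with the deficit moved to its sister branch, preserving
path lengths. Trees are ladderized (children sorted by subtree leaf
count, ties by smallest leaf label) before serialization, fixing both
the Newick string (branch lengths at 6 significant digits) and the
left-to-right leaf order that heat maps reuse as row order.
Robinson–Foulds distance counts non-trivial bipartitions present in
exactly one tree; a test cross-checks it against dendropy.

On additive matrices NJ is consistent; the suite verifies exact
topology recovery (RF = 0) over 100 random trees with n ≤ 12 and
path-length reproduction to 1e-9.

## ANI estimation and heat-map normalisation

ANI operates on the concatenated CDS of each genome (concatenation in
annotation order, no separators). The query concatenate is cut into
1 kb fragments (final fragment kept if ≥ 500 bp). Per fragment, the
containment j of its 16-mers in the reference's 16-mer set is converted
to an identity by the Mash transform
`identity = 100·(1 + (1/16)·ln(2j/(1+j)))`, clamped to [0, 100];
fragments with j < 0.01 are unmapped. ANI is the mean identity of
mapped fragments, and is directional (query → reference), so the matrix
is generally asymmetric. This estimator deliberately omits minimizer
sampling and reciprocal-mapping filters of dedicated ANI tools: it
shares their input/output contract and monotone response to divergence
(verified by simulation: Spearman ρ < −0.95 across substitution rates
0–0.10), but its absolute values are its own. Self-ANI is exactly 100.
Fragments are taken on the forward strand (the generator emits CDS in
consistent orientation); reverse-complement k-mer canonicalization is
available as a flag for real data.

For heat maps, dissimilarity = 100 − ANI; unmapped pairs take their
triangle's maximum so the map stays total. The strict lower and strict
upper triangles are each divided by their own mean (making both means
exactly 1 — the operation is idempotent), the diagonal is zeroed, and
rows/columns are permuted to the leaf order of an NJ dendrogram. NJ
needs a symmetric input, so the dendrogram is built on the symmetrized
matrix (M + Mᵀ)/2 of the normalized dissimilarity.

## Marker panels, diazotrophy, donor attribution

A panel is a FASTA of reference proteins (record id = marker id). Per
genome and marker, homology is the maximum clustering similarity over
the genome's proteins (the same 0–1 self-normalized scale, for internal
consistency across analyses); values below a 0.05 floor are reported as
0 (noise-level k-mer overlap), and the best-hit protein is recorded.
Diazotrophy requires *all six* minimal-set genes (*nifH, nifD, nifK,
nifE, nifN, nifB*) at homology ≥ 0.7 (aligned with the clustering
threshold; configurable). Donor attribution scores the genome against
two or more donor panels sharing the same marker set: non-diazotrophs
(judged on their best panel) get origin "none"; otherwise the donor
with the greatest mean homology wins unless the top two means are
within 0.02, which is reported "ambiguous". The call is invariant under
panel listing order. Best-hit-only reporting means multi-copy *nifH*
genomes contribute their closest copy.

## Synthetic data generator

The generator emulates a small genome collection of the kind used for
genus delineation, at desk scale:

- **Tree.** Yule process from 2 lineages (waiting times exponential
  with rate `birth_rate × lineage count`, uniformly chosen splitter)
  until n = 16 leaves, plus one extra waiting time so sister tips are
  not identical; branch lengths multiplied by `branch_scale` to give
  substitutions/site. The three lineages alive after the first split
  define the three clades.
- **Sequences.** Gene roots are uniform random sense codons (length
  uniform in ±30 % of 300 codons, minimum 60). Along each branch of
  length t every site substitutes with probability 1 − e^(−t),
  uniformly to one of the three alternatives; substitutions creating
  stop codons are redrawn (always possible: no three stop codons share
  two positions). For small per-branch lengths this matches the
  Jukes–Cantor expectation, which a 10 kb test verifies to 3 standard
  errors. Proteins are standard-code translations; internal stops are
  impossible by construction.
- **Gene content.** 50 core families in every genome; 30 accessory
  families each lost independently on every branch with probability
  0.15 (loss inherited by descendants), so presence patterns are
  phylogenetically structured as in real pan-genomes. The truth bundle
  records the *realized* core — families actually present in all
  genomes, including the occasional accessory family that escaped loss
  everywhere — because that is what any content-based core definition
  can see.
- ***nif* cassette.** A 6-gene ancestral cassette is evolved into two
  donor copies 0.30 substitutions/site apart. Each donor's cassette is
  transferred once into the ancestor of its recipient clade (stem
  divergence 0.02) and then descends vertically along that clade —
  a single HGT event per clade, so cassette sequences carry
  tree-consistent signal while remaining donor-attributable. The third
  clade receives no cassette. Donor panels are written as protein
  FASTA.
- **Defaults as study conditions.** `branch_scale` defaults to 0.003
  substitutions/site per unit of tree time. With typical Yule tree
  depths (~2.3 time units) this keeps maximum within-family amino-acid
  divergence near 5 %, the regime in which the 3-mer/0.7 clustering
  score reliably keeps families intact (calibrated once over 30 seeds:
  exact core recovery and 16/16 donor attribution in all of them).
  It also puts between-clade ANI around 98 %, i.e. congeneric species
  territory.
- **Determinism.** All randomness flows from one seed through named
  `SeedSequence` substreams; identical configs reproduce every output
  file byte for byte.

What the generator does **not** emulate: realistic codon usage and
GC content, indels (an option exists but is off: the k-mer similarity
regime is calibrated for substitution-only divergence), recombination,
rearrangement, intergenic DNA, and annotation noise. Tests passing on
this generator therefore demonstrate the correctness and calibration of
the analysis chain under its stated model, not performance on real
annotations.

## Known limitations

- **Short-branch tree recovery.** With ~80 genes × 300 codons
  (~72 kb) per genome, internal tree branches below ~10⁻⁴
  substitutions/site carry at most a few substitutions; Yule trees
  regularly contain such branches, and no distance method can resolve
  them reliably at this sequence length — NJ on exact nucleotide
  Hamming distances fails the same trees. Per-branch accessory loss
  adds a further length-independent perturbation (one gene
  presence/absence difference moves squared vector distances as much
  as ~28 substitutions), and the p = 1369 projection contributes ~2 %
  distance distortion. Whole-proteome NJ therefore recovers the exact
  topology on only a fraction of default-condition datasets (typically
  RF 0–4 out of 26 bipartitions); clade-level structure is essentially
  always correct. Exact recovery would require either longer genomes
  or divergences too large for the clustering threshold, a trade-off
  inherent to the miniature scale.
- The ANI estimator and the clustering score are internally consistent
  stand-ins; absolute agreement with FastANI/BLAST-based tools on real
  data is out of scope.
- Panels are scored by best hit only; multi-copy reporting exists but
  without a calibrated contract.

## Pipeline and reproducibility

The `arcgen` CLI orchestrates simulate → cluster → core → vectors →
tree → ani → panels, each stage reading only plain-text artifacts of
earlier stages (TSV/Newick/JSON), exiting 2 with a message naming the
missing stage when run out of order. TSV artifacts carry a header with
the tool version, a hash of the analysis parameters (file locations
excluded) and the seed. Two runs with identical config and seed are
byte-identical except for `run.log` (wall-clock timings) and the echoed
config (absolute paths). Problem sizes throughout the test suite and
acceptance script (16 genomes, 80 families, 5 replicate seeds) were
chosen so the full verification chain runs in a couple of minutes on a
single CPU.
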