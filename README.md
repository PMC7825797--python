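# arcgen

Alignment-free comparative genomics for bacterial genome collections —
the kind of analysis used to delineate genera such as
*Azoarcus*/*Aromatoleum* and to trace the origin of horizontally
acquired nitrogen-fixation (*nif*) genes.

Given per-genome protein FASTA (`.faa`) and CDS FASTA (`.fna`) files,
the package computes, without any sequence alignment:

- **Whole-proteome vectors and NJ phylogenomics.** Every proteome is
  reduced to a single fixed-length vector: spaced words are read at the
  care positions of the binary mask `11011` slid over each protein,
  their binary occurrence vector over the 20⁴ word space is projected
  to *p* = 1369 dimensions (37², convenient for visualisation) by a
  seeded Gaussian random projection, and Euclidean distances between
  vectors feed a Saitou–Nei neighbour-joining tree
  (Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k)).
- **Greedy protein clustering and the core genome.** All proteins are
  partitioned longest-first by a self-normalized shared 3-mer score
  (s(a,b) = |K(a)∩K(b)| / min(|K(a)|,|K(b)|), so s(x,x) = 1) at a 0.7
  join threshold; the presence matrix of cluster × genome member counts
  yields the core genome (clusters present in every genome).
- **ANI dissimilarity heat maps.** Average nucleotide identity per
  ordered genome pair from 1 kb fragments of the concatenated CDS
  mapped by 16-mer containment *j* and the Mash identity transform
  (identity = 100·(1 + (1/k)·ln(2j/(1+j)))); dissimilarity (100 − ANI)
  with each strict triangle normalised to mean 1, rows and columns
  ordered by an NJ dendrogram.
- **Marker-gene panels and *nif* origin.** Per-genome best-hit homology
  against marker panels (*nif*, *nar*/*nap*/*nir*/*nor*/*nos*,
  *bzd*/*box*, ...); diazotrophy is called when the full minimal *nif*
  set (*nifH, nifD, nifK, nifE, nifN, nifB*) is present at ≥ 0.7
  homology, and the cassette is attributed to whichever donor reference
  set (e.g. *Azospira*-type vs *Dechloromonas*-type) has the greater
  mean homology.
- **A truth-tracked synthetic-genome generator.** Yule trees with three
  clades, Jukes–Cantor-style codon-aware sequence evolution, core and
  branch-wise-lost accessory families, and a 6-gene *nif* cassette
  transferred from one of two divergent donors — so every stage can be
  scored against known truth without downloading genomes.

## Worked example

```sh
python examples/simulate_dataset.py
python examples/cluster_and_core.py
python examples/nif_origin_calls.py
```

prints (abridged):

```
core families: 50
clades: {'clade1': 5, 'clade2': 2, 'clade3': 9}
nif recipients: 7 of 16 genomes

1080 proteins -> 91 clusters
  multi-member clusters: 90 (99.91% of sequences)
  singletons:            1 (0.09% of sequences)
core genome: 50 clusters present in all 16 genomes (74.07% of sequences)

G01: diazotroph=True  origin=donorA (donorA=0.852, donorB=0.189) [ok]
...
16/16 origin calls match the simulation truth
```

The 91 clusters are the 50 core families, 29 surviving accessory
families and the two donor-specific *nif* cassettes (6 genes each);
recovering 50/50 core clusters and 16/16 origin calls means clustering,
core extraction and donor attribution reproduced the generator's truth
exactly. The origin call rests on mean homology ≈ 0.85 to the true
donor versus ≈ 0.19 to the 30 %-diverged alternative.

The same analyses run from a shell:

```sh
arcgen all --output-dir out --seed 7        # simulate + full chain
arcgen ani --output-dir out                 # re-run one stage
```

writing plain TSV/Newick/JSON artifacts (`clusters.tsv`, `core.tsv`,
`dist_whole.tsv`, `tree_whole.nwk`, `ani_heatmap.tsv`,
`nif_origin.json`, ...) that are byte-identical across reruns of the
same config and seed.

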