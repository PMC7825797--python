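"""Greedy protein clustering and core-genome extraction.

Clusters every protein of the collection at the 0.7 self-normalized
similarity threshold, then extracts the clusters present in all genomes
(the core genome) and their share of sequences.
"""

import os

from arcgen import (
    SimulationConfig,
    cluster_stats,
    core_clusters,
    generate_dataset,
    greedy_cluster,
    load_genome_set,
    presence_matrix,
)

outdir = "scratch/example_dataset"
if not os.path.exists(os.path.join(outdir, "manifest.tsv")):
    generate_dataset(SimulationConfig(seed=7), outdir)

gs = load_genome_set(os.path.join(outdir, "manifest.tsv"))
clusters = greedy_cluster(gs)
stats = cluster_stats(clusters)
print(f"{clusters.n_members} proteins -> {len(clusters)} clusters")
print(f"  multi-member clusters: {stats['n_clusters_ge2']} "
      f"({stats['pct_sequences_ge2']}% of sequences)")
print(f"  singletons:            {stats['n_singletons']} "
      f"({stats['pct_sequences_singleton']}% of sequences)")

core = core_clusters(presence_matrix(clusters, gs))
print(f"core genome: {core.n_core} clusters present in all {len(gs)} genomes "
      f"({core.pct_core_sequences}% of sequences)")

# A cluster is "core" when every genome contributes at least one member;
# the percentage is the fraction of all protein sequences that live in
# core clusters.
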