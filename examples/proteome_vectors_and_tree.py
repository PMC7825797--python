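"""Whole-proteome spaced-word vectors and the NJ phylogeny.

Each proteome becomes a 1369-dimensional vector (mask 11011, Gaussian
random projection of the spaced-word occurrence vector); Euclidean
distances between vectors feed neighbour joining.
"""

import os

from arcgen import (
    SimulationConfig,
    generate_dataset,
    load_genome_set,
    neighbor_joining,
    pairwise_distances,
    read_newick,
    robinson_foulds,
    to_newick,
    vectorize_genome_set,
)
from arcgen.synthetic_data import load_truth

outdir = "scratch/example_dataset"
if not os.path.exists(os.path.join(outdir, "manifest.tsv")):
    generate_dataset(SimulationConfig(seed=7), outdir)

gs = load_genome_set(os.path.join(outdir, "manifest.tsv"))
vectors = vectorize_genome_set(gs)  # defaults: mask 11011, p=1369
print(f"{len(vectors)} vectors of length {len(vectors[0].values)}")

dm = pairwise_distances(vectors)
tree = neighbor_joining(dm)
print("NJ tree:", to_newick(tree)[:90], "...")

truth = load_truth(os.path.join(outdir, "truth.json"))
rf = robinson_foulds(tree, read_newick(truth.true_tree))
print(f"Robinson-Foulds distance to the true tree: {rf}")
# RF = 0 means the estimated topology matches the simulation's tree
# exactly; each unit of RF is one bipartition found in only one tree.
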