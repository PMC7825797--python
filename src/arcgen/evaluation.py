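"""Recovery scoring of pipeline results against generator truth.

Given a synthetic dataset directory (FASTA files, manifest, donor
panels, truth JSON), run the analysis chain in memory and score how well
each stage recovers the known truth: tree topology (Robinson-Foulds),
core-family set, diazotrophy calls (sensitivity/specificity) and nif
donor attribution.
"""

from __future__ import annotations

import os

from .gene_panels import assign_origin, load_panel
from .pangenome import core_clusters
from .phylogeny import neighbor_joining, read_newick, robinson_foulds
from .protein_clustering import SimilarityParams, greedy_cluster, presence_matrix
from .sequence_io import load_genome_set
from .sweep_vectors import (
    SpacedWordMask,
    make_projection,
    pairwise_distances,
    vectorize_genome_set,
)
from .synthetic_data import TruthBundle, load_truth


def evaluate_recovery(
    dataset_dir: str,
    truth: TruthBundle | None = None,
    mask: SpacedWordMask | None = None,
    projection_size: int = 1369,
    projection_seed: int = 20210107,
    params: SimilarityParams = SimilarityParams(),
) -> dict:
    """Score tree, core, diazotrophy and donor recovery on one dataset.

    Returns a dict with ``rf_whole`` (Robinson-Foulds distance between
    the NJ tree of whole-proteome vectors and the true tree),
    ``core_exact`` (recovered core clusters correspond one-to-one to the
    true core families), ``diazotroph_sensitivity`` / ``_specificity``,
    and ``origin_accuracy`` (fraction of genomes whose donor call
    matches truth, "none" included).
    """
    truth = truth or load_truth(os.path.join(dataset_dir, "truth.json"))
    gs = load_genome_set(os.path.join(dataset_dir, "manifest.tsv"))
    t_true = read_newick(truth.true_tree)

    mask = mask or SpacedWordMask()
    proj = make_projection(mask.weight, projection_size, projection_seed)
    vectors = vectorize_genome_set(gs, mask, proj)
    t_est = neighbor_joining(pairwise_distances(vectors))
    rf = robinson_foulds(t_est, t_true)

    clusters = greedy_cluster(gs, params)
    pm = presence_matrix(clusters, gs)
    core = core_clusters(pm)
    fam_of = {
        c.cluster_id: {pid for _, pid in c.members} for c in clusters.clusters
    }
    pure = all(len(fam_of[cid]) == 1 for cid in core.core_cluster_ids)
    recovered = (
        set().union(*(fam_of[cid] for cid in core.core_cluster_ids))
        if core.core_cluster_ids
        else set()
    )
    core_exact = pure and recovered == set(truth.core_family_ids)

    donor_panels = [
        load_panel(os.path.join(dataset_dir, fname), donor)
        for donor, fname in sorted(truth.donor_panel_files.items())
    ]
    tp = tn = fp = fn = correct = 0
    for genome in gs:
        call = assign_origin(genome, donor_panels, params)
        true_donor = truth.nif_origin[genome.genome_id]
        if true_donor is None:
            tn += not call.is_diazotroph
            fp += call.is_diazotroph
        else:
            tp += call.is_diazotroph
            fn += not call.is_diazotroph
        correct += call.origin == (true_donor or "none")
    n = len(gs)
    return {
        "n_genomes": n,
        "rf_whole": rf,
        "core_exact": bool(core_exact),
        "n_core": core.n_core,
        "diazotroph_sensitivity": tp / (tp + fn) if tp + fn else 1.0,
        "diazotroph_specificity": tn / (tn + fp) if tn + fp else 1.0,
        "origin_accuracy": correct / n,
    }
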