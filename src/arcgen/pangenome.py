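"""Core-genome extraction from the cluster presence matrix.

The core genome is the set of protein clusters represented (>= 1 member,
paralogs allowed) in every genome of the collection.  For the core-genome
phylogeny each genome contributes one representative protein per core
cluster: its longest member there, with lexicographic protein-id
tie-breaking, so core proteomes stay comparable when paralog counts
differ.
"""

from __future__ import annotations

from dataclasses import dataclass

from .protein_clustering import ClusterSet, PresenceMatrix
from .sequence_io import GenomeProteome


@dataclass
class CoreGenomeResult:
    core_cluster_ids: list[int]
    n_core: int
    pct_core_sequences: float


def core_clusters(
    pm: PresenceMatrix, single_copy: bool = False
) -> CoreGenomeResult:
    """Clusters present in every genome, and their share of sequences.

    ``single_copy=True`` additionally requires exactly one member per
    genome (off by default: multi-copy core clusters are legitimate).
    """
    counts = pm.counts
    if counts.empty:
        raise ValueError("empty presence matrix")
    if single_copy:
        mask = (counts == 1).all(axis=1)
    else:
        mask = (counts >= 1).all(axis=1)
    core_ids = list(counts.index[mask])
    total = int(counts.to_numpy().sum())
    in_core = int(counts.loc[core_ids].to_numpy().sum()) if core_ids else 0
    pct = round(100.0 * in_core / total, 2) if total else 0.0
    return CoreGenomeResult(core_ids, len(core_ids), pct)


def core_proteome(
    genome: GenomeProteome, core: CoreGenomeResult, clusters: ClusterSet
) -> GenomeProteome:
    """One representative protein of this genome per core cluster.

    For each core cluster the genome's longest member is selected (ties
    broken by smallest protein_id); output follows core cluster_id order.
    """
    by_id = {rec.id: rec for rec in genome.proteins}
    cluster_by_id = {c.cluster_id: c for c in clusters.clusters}
    selected = []
    for cid in core.core_cluster_ids:
        members = [
            pid for gid, pid in cluster_by_id[cid].members
            if gid == genome.genome_id
        ]
        assert members, (
            f"genome {genome.genome_id!r} missing from core cluster {cid}"
        )
        members.sort(key=lambda pid: (-len(by_id[pid].residues), pid))
        selected.append(by_id[members[0]])
    return GenomeProteome(genome.genome_id, selected, cds=None)


def write_core_tsv(core: CoreGenomeResult, path, header_comment: str = "") -> None:
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        out.write(f"# n_core={core.n_core} pct_core_sequences={core.pct_core_sequences}\n")
        out.write("cluster_id\n")
        for cid in core.core_cluster_ids:
            out.write(f"{cid}\n")
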