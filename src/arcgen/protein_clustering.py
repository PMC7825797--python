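"""Greedy alignment-free protein clustering.

All proteins of a genome collection are partitioned by a single greedy
pass: proteins are visited longest-first and each either joins the
existing cluster whose representative it matches best (if that best
normalized similarity reaches the threshold) or founds a new cluster.
The similarity is the shared 3-mer fraction normalized by the smaller
k-mer set, so any sequence scores exactly 1 against itself (the
"self-score" anchor) and the 0.7 default threshold is expressed on that
self-normalized scale.  The resulting presence matrix (cluster x genome
member counts) underlies the core-genome and marker-panel analyses.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .sequence_io import GenomeSet, SequenceRecord


@dataclass(frozen=True)
class SimilarityParams:
    kmer_len: int = 3
    threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.kmer_len < 1:
            raise ValueError("kmer_len must be positive")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


def kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def similarity(
    a: SequenceRecord, b: SequenceRecord, params: SimilarityParams = SimilarityParams()
) -> float:
    """Min-normalized shared-k-mer similarity in [0, 1].

    ``|Kmers(a) & Kmers(b)| / min(|Kmers(a)|, |Kmers(b)|)`` over contiguous
    k-mer sets.  Symmetric; identical sequences (with at least one k-mer)
    score 1.  Sequences shorter than k have no k-mers and score 0 against
    everything.
    """
    ka = kmer_set(a.residues, params.kmer_len)
    kb = kmer_set(b.residues, params.kmer_len)
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


@dataclass
class ProteinCluster:
    cluster_id: int
    representative: tuple[str, str]  # (genome_id, protein_id)
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[ProteinCluster]
    params: SimilarityParams

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_members(self) -> int:
        return sum(c.size for c in self.clusters)


def _ordered_proteins(gs: GenomeSet) -> list[tuple[str, SequenceRecord]]:
    """Content-based processing order: descending length, then ids."""
    items = [
        (gid, rec) for gid, genome in gs.genomes.items() for rec in genome.proteins
    ]
    items.sort(key=lambda t: (-len(t[1].residues), t[0], t[1].id))
    return items


def greedy_cluster(
    gs: GenomeSet,
    params: SimilarityParams = SimilarityParams(),
    prefilter: bool = True,
) -> ClusterSet:
    """Single-pass greedy clustering of every protein in the genome set.

    Each protein is compared against cluster REPRESENTATIVES only; it
    joins the cluster maximizing the similarity when that maximum is
    >= ``params.threshold`` (ties resolved to the lowest cluster_id),
    otherwise it founds a new cluster.  ``prefilter`` consults a shared
    k-mer inverted index so only representatives sharing at least one
    k-mer are scored; this cannot change the result because a zero-overlap
    pair scores 0.
    """
    k = params.kmer_len
    clusters: list[ProteinCluster] = []
    rep_kmers: list[frozenset[str]] = []
    index: dict[str, list[int]] = defaultdict(list)  # kmer -> cluster ids

    for gid, rec in _ordered_proteins(gs):
        kms = kmer_set(rec.residues, k)
        best_id = -1
        best_sim = 0.0
        if kms:
            if prefilter:
                cand = set()
                for km in kms:
                    cand.update(index.get(km, ()))
                candidates = sorted(cand)
            else:
                candidates = range(len(clusters))
            for cid in candidates:
                rk = rep_kmers[cid]
                if not rk:
                    continue
                sim = len(kms & rk) / min(len(kms), len(rk))
                if sim > best_sim:  # ties keep the lowest cluster_id
                    best_sim = sim
                    best_id = cid
        if best_id >= 0 and best_sim >= params.threshold:
            clusters[best_id].members.append((gid, rec.id))
        else:
            cid = len(clusters)
            clusters.append(ProteinCluster(cid, (gid, rec.id), [(gid, rec.id)]))
            rep_kmers.append(kms)
            for km in kms:
                index[km].append(cid)
    return ClusterSet(clusters, params)


@dataclass
class PresenceMatrix:
    """Cluster-by-genome member counts as a pandas DataFrame."""

    counts: pd.DataFrame  # index: cluster_id, columns: genome_id

    @property
    def cluster_ids(self) -> list[int]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)


def presence_matrix(clusters: ClusterSet, gs: GenomeSet) -> PresenceMatrix:
    """counts[c, g] = number of members of cluster c from genome g."""
    gids = gs.genome_ids
    gset = set(gids)
    df = pd.DataFrame(
        0, index=[c.cluster_id for c in clusters.clusters], columns=gids, dtype=int
    )
    for c in clusters.clusters:
        for gid, _pid in c.members:
            if gid not in gset:
                raise ValueError(f"cluster member genome {gid!r} not in genome set")
            df.at[c.cluster_id, gid] += 1
    return PresenceMatrix(df)


def cluster_percentages(n_sequences: int, n_singleton_clusters: int) -> tuple[float, float]:
    """Percent of sequences in multi-member clusters vs singletons.

    Singleton clusters hold exactly one sequence each, so the singleton
    share of sequences is ``n_singleton_clusters / n_sequences``.
    Percentages are rounded to 2 decimals.
    """
    pct_singleton = round(100.0 * n_singleton_clusters / n_sequences, 2)
    pct_ge2 = round(100.0 * (n_sequences - n_singleton_clusters) / n_sequences, 2)
    return pct_ge2, pct_singleton


def cluster_stats(clusters: ClusterSet) -> dict:
    """Summary counts and 2-decimal sequence percentages."""
    if not clusters.clusters:
        raise ValueError("empty cluster set")
    n_singletons = sum(1 for c in clusters.clusters if c.size == 1)
    n_ge2 = len(clusters.clusters) - n_singletons
    total = clusters.n_members
    pct_ge2, pct_singleton = cluster_percentages(total, n_singletons)
    return {
        "n_clusters_ge2": n_ge2,
        "n_singletons": n_singletons,
        "pct_sequences_ge2": pct_ge2,
        "pct_sequences_singleton": pct_singleton,
    }


def write_clusters_tsv(clusters: ClusterSet, path, header_comment: str = "") -> None:
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        out.write("cluster_id\trepresentative\tsize\tmembers\n")
        for c in clusters.clusters:
            rep = f"{c.representative[0]}:{c.representative[1]}"
            members = ",".join(f"{g}:{p}" for g, p in c.members)
            out.write(f"{c.cluster_id}\t{rep}\t{c.size}\t{members}\n")


def write_presence_tsv(pm: PresenceMatrix, path, header_comment: str = "") -> None:
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        pm.counts.rename_axis("cluster_id").to_csv(out, sep="\t")
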