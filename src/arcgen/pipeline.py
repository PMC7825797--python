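"""Stage orchestration behind the ``arcgen`` command-line tool.

Each stage reads plain-text artifacts written by earlier stages
(TSV/Newick/JSON only), so any stage can be re-run or inspected in
isolation.  All randomness derives from the single config seed through
named substreams; two runs with the same config produce byte-identical
TSV and Newick artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .ani import (
    AniParams,
    ani_matrix,
    heatmap_matrix,
    normalize_dissimilarity,
    symmetrized,
    write_ani_tsv,
    write_matrix_tsv,
)
from .gene_panels import (
    MINIMAL_NIF_SET,
    assign_origin,
    hit_matrix,
    load_panel,
    panel_heatmap,
    write_origin_calls,
)
from .pangenome import core_clusters, core_proteome, write_core_tsv
from .phylogeny import leaf_order, neighbor_joining, read_newick, write_newick
from .protein_clustering import (
    ClusterSet,
    ProteinCluster,
    SimilarityParams,
    greedy_cluster,
    presence_matrix,
    write_clusters_tsv,
    write_presence_tsv,
)
from .sequence_io import GenomeSet, load_genome_set, write_fasta
from .sweep_vectors import (
    DistanceMatrix,
    SpacedWordMask,
    kmeans_groups,
    make_projection,
    pairwise_distances,
    vectorize_genome_set,
    write_distance_tsv,
    write_vectors_tsv,
)
from .synthetic_data import SimulationConfig, generate_dataset

log = logging.getLogger("arcgen")

STAGES = ("simulate", "cluster", "core", "vectors", "tree", "ani", "panels")


class MissingPrerequisite(RuntimeError):
    """A stage was invoked before the stage that produces its inputs."""

    def __init__(self, artifact: str, stage: str):
        super().__init__(
            f"missing artifact {artifact!r}: run the {stage!r} stage first"
        )
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis parameters."""

    output_dir: str
    manifest: str | None = None
    mask: str = "11011"
    projection_size: int = 1369
    projection_seed: int = 20210107
    clustering_kmer_len: int = 3
    clustering_threshold: float = 0.7
    ani_fragment_len: int = 1000
    ani_kmer_len: int = 16
    ani_min_jaccard: float = 0.01
    panel_paths: list[str] = field(default_factory=list)
    donor_panel_paths: list[str] = field(default_factory=list)
    kmeans_k: int = 4
    seed: int = 1
    log_level: str = "INFO"
    # simulate-stage parameters (used only by the simulate stage)
    sim_n_genomes: int = 16
    sim_n_core_families: int = 50
    sim_n_accessory_families: int = 30
    sim_accessory_loss_prob: float = 0.15
    sim_mean_gene_len: int = 300
    sim_branch_scale: float = 0.003
    sim_donor_divergence: float = 0.30
    sim_recipient_extra_divergence: float = 0.02

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (not file locations)."""
        payload = {
            k: v
            for k, v in self.to_dict().items()
            if k not in ("output_dir", "manifest", "log_level")
        }
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.md5(canonical.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"arcgen {__version__} config={self.config_hash()} seed={self.seed}"

    def path(self, *parts: str) -> str:
        return os.path.join(self.output_dir, *parts)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            n_genomes=self.sim_n_genomes,
            n_core_families=self.sim_n_core_families,
            n_accessory_families=self.sim_n_accessory_families,
            accessory_loss_prob=self.sim_accessory_loss_prob,
            mean_gene_len=self.sim_mean_gene_len,
            branch_scale=self.sim_branch_scale,
            donor_divergence=self.sim_donor_divergence,
            recipient_extra_divergence=self.sim_recipient_extra_divergence,
        )

    def similarity_params(self) -> SimilarityParams:
        return SimilarityParams(self.clustering_kmer_len, self.clustering_threshold)

    def ani_params(self) -> AniParams:
        return AniParams(
            self.ani_fragment_len, self.ani_kmer_len, self.ani_min_jaccard
        )


def _require(cfg: RunConfig, artifact: str, stage: str) -> str:
    path = cfg.path(artifact)
    if not os.path.exists(path):
        raise MissingPrerequisite(artifact, stage)
    return path


def _load_genomes(cfg: RunConfig) -> GenomeSet:
    manifest = cfg.manifest
    if manifest is None:
        manifest = cfg.path("data", "manifest.tsv")
        if not os.path.exists(manifest):
            raise MissingPrerequisite("data/manifest.tsv", "simulate")
    elif not os.path.exists(manifest):
        raise FileNotFoundError(f"manifest not found: {manifest}")
    return load_genome_set(manifest)


def read_clusters_tsv(path: str, params: SimilarityParams) -> ClusterSet:
    clusters = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("cluster_id\t"):
                continue
            cid, rep, _size, members = line.rstrip("\n").split("\t")
            rep_g, rep_p = rep.split(":", 1)
            member_list = [
                tuple(m.split(":", 1)) for m in members.split(",") if m
            ]
            clusters.append(ProteinCluster(int(cid), (rep_g, rep_p), member_list))
    return ClusterSet(clusters, params)


def read_distance_tsv(path: str) -> DistanceMatrix:
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")[1:]
    for ln in lines[1:]:
        parts = ln.rstrip("\n").split("\t")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    assert labels == header
    return DistanceMatrix(labels, np.array(rows))


def stage_simulate(cfg: RunConfig) -> None:
    outdir = cfg.path("data")
    truth = generate_dataset(cfg.sim_config(), outdir)
    log.info("simulate: %d genomes, %d core families written to %s",
             cfg.sim_n_genomes, len(truth.core_family_ids), outdir)


def stage_cluster(cfg: RunConfig) -> None:
    gs = _load_genomes(cfg)
    clusters = greedy_cluster(gs, cfg.similarity_params())
    pm = presence_matrix(clusters, gs)
    write_clusters_tsv(clusters, cfg.path("clusters.tsv"), cfg.header())
    write_presence_tsv(pm, cfg.path("presence.tsv"), cfg.header())
    log.info("cluster: %d proteins -> %d clusters", clusters.n_members,
             len(clusters))


def stage_core(cfg: RunConfig) -> None:
    gs = _load_genomes(cfg)
    clusters = read_clusters_tsv(
        _require(cfg, "clusters.tsv", "cluster"), cfg.similarity_params()
    )
    pm = presence_matrix(clusters, gs)
    core = core_clusters(pm)
    write_core_tsv(core, cfg.path("core.tsv"), cfg.header())
    core_dir = cfg.path("core_faa")
    os.makedirs(core_dir, exist_ok=True)
    for genome in gs:
        cp = core_proteome(genome, core, clusters)
        write_fasta(cp.proteins, os.path.join(core_dir, f"{genome.genome_id}.faa"))
    log.info("core: %d of %d clusters (%s%% of sequences)", core.n_core,
             len(clusters), core.pct_core_sequences)


def stage_vectors(cfg: RunConfig) -> None:
    gs = _load_genomes(cfg)
    mask = SpacedWordMask(cfg.mask)
    proj = make_projection(mask.weight, cfg.projection_size, cfg.projection_seed)
    vectors = vectorize_genome_set(gs, mask, proj)
    write_vectors_tsv(vectors, cfg.path("vectors.tsv"))
    dm = pairwise_distances(vectors)
    write_distance_tsv(dm, cfg.path("dist_whole.tsv"), cfg.header())
    if len(vectors) >= cfg.kmeans_k:
        labels, coords = kmeans_groups(vectors, cfg.kmeans_k, cfg.seed)
        with open(cfg.path("kmeans.tsv"), "w") as out:
            out.write(f"# {cfg.header()}\n")
            out.write("genome_id\tcluster\tpc1\tpc2\n")
            for v, lab, (x, y) in zip(vectors, labels, coords):
                out.write(f"{v.genome_id}\t{int(lab)}\t{x!r}\t{y!r}\n")
    # core-genome vectors from the per-genome core proteomes
    clusters = read_clusters_tsv(
        _require(cfg, "clusters.tsv", "cluster"), cfg.similarity_params()
    )
    _require(cfg, "core.tsv", "core")
    pm = presence_matrix(clusters, gs)
    core = core_clusters(pm)
    core_proteomes = [core_proteome(g, core, clusters) for g in gs]
    if core.n_core:
        core_vectors = vectorize_genome_set(core_proteomes, mask, proj)
        dm_core = pairwise_distances(core_vectors)
        write_distance_tsv(dm_core, cfg.path("dist_core.tsv"), cfg.header())
    log.info("vectors: %d genomes, p=%d", len(gs), cfg.projection_size)


def stage_tree(cfg: RunConfig) -> None:
    dm = read_distance_tsv(_require(cfg, "dist_whole.tsv", "vectors"))
    tree = neighbor_joining(dm)
    write_newick(tree, cfg.path("tree_whole.nwk"))
    core_dist = cfg.path("dist_core.tsv")
    if os.path.exists(core_dist):
        tree_core = neighbor_joining(read_distance_tsv(core_dist))
        write_newick(tree_core, cfg.path("tree_core.nwk"))
    log.info("tree: NJ over %d taxa", len(dm.labels))


def stage_ani(cfg: RunConfig) -> None:
    gs = _load_genomes(cfg)
    am = ani_matrix(gs, cfg.ani_params())
    write_ani_tsv(am, cfg.path("ani.tsv"), cfg.header())
    nd = normalize_dissimilarity(am)
    write_matrix_tsv(
        __import__("pandas").DataFrame(nd.M, index=nd.labels, columns=nd.labels),
        cfg.path("ani_norm.tsv"),
        cfg.header(),
    )
    order = leaf_order(neighbor_joining(symmetrized(nd)))
    write_matrix_tsv(heatmap_matrix(nd, order), cfg.path("ani_heatmap.tsv"),
                     cfg.header())
    log.info("ani: %d x %d matrix", len(nd.labels), len(nd.labels))


def _panel_paths(cfg: RunConfig) -> tuple[list[str], list[str]]:
    """Configured panels, falling back to the simulate stage's donor
    panels (recorded in the dataset's truth JSON) when none are given."""
    panels = list(cfg.panel_paths)
    donors = list(cfg.donor_panel_paths)
    truth_path = cfg.path("data", "truth.json")
    if not donors and os.path.exists(truth_path):
        with open(truth_path) as fh:
            truth = json.load(fh)
        donors = [
            cfg.path("data", f)
            for _, f in sorted(truth.get("donor_panel_files", {}).items())
        ]
    if not panels:
        panels = list(donors)
    return panels, donors


def stage_panels(cfg: RunConfig) -> None:
    gs = _load_genomes(cfg)
    panel_paths, donor_paths = _panel_paths(cfg)
    tree_path = _require(cfg, "tree_whole.nwk", "tree")
    order = leaf_order(read_newick(tree_path))
    os.makedirs(cfg.path("panels"), exist_ok=True)
    params = cfg.similarity_params()
    for panel_path in panel_paths:
        panel = load_panel(panel_path)
        hm = hit_matrix(gs, panel, params)
        write_matrix_tsv(
            panel_heatmap(hm, order),
            cfg.path("panels", f"{panel.panel_id}.tsv"),
            cfg.header(),
        )
    if len(donor_paths) >= 2:
        donor_panels = [load_panel(p) for p in donor_paths]
        calls = [
            assign_origin(g, donor_panels, params,
                          presence_threshold=cfg.clustering_threshold)
            for g in gs
        ]
        write_origin_calls(calls, cfg.path("nif_origin.json"))
        log.info("panels: %d/%d diazotrophs",
                 sum(c.is_diazotroph for c in calls), len(calls))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "cluster": stage_cluster,
    "core": stage_core,
    "vectors": stage_vectors,
    "tree": stage_tree,
    "ani": stage_ani,
    "panels": stage_panels,
}


def run(subcommand: str, cfg: RunConfig) -> int:
    """Execute one stage (or ``all``); returns a process exit code."""
    if subcommand != "all" and subcommand not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {subcommand!r}")
    os.makedirs(cfg.output_dir, exist_ok=True)
    handler = logging.FileHandler(cfg.path("run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    with open(cfg.path("config_echo.yaml"), "w") as out:
        yaml.safe_dump(cfg.to_dict(), out, sort_keys=True)
    stages = list(STAGES) if subcommand == "all" else [subcommand]
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](cfg)
            log.info("%s finished in %.2fs", stage, time.perf_counter() - t0)
    except MissingPrerequisite as exc:
        log.error("%s", exc)
        return 2
    except Exception as exc:  # logged reason, non-zero exit
        log.error("pipeline failed: %s", exc)
        return 1
    finally:
        log.removeHandler(handler)
        handler.close()
    return 0
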