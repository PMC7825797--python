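"""Synthetic genome collections with known truth.

Emulates the statistical structure of a small bacterial genome
collection: a Yule tree over the genomes with three major clades, a set
of core gene families present everywhere, accessory families lost
independently on branches (so presence patterns are phylogenetically
structured), and a 6-gene nif cassette (nifH, nifD, nifK, nifE, nifN,
nifB) horizontally acquired from one of two divergent donor lineages.
Sequences evolve at the nucleotide level under a Jukes-Cantor-style
model with stop-codon avoidance and are translated, so one truth serves
both the nucleotide (ANI) and protein (clustering / vectors / panels)
analyses.

Every output is a plain-text file — per-genome ``.faa``/``.fna``, a
manifest TSV, two donor panel FASTAs and a truth JSON — directly
consumable by :func:`arcgen.sequence_io.load_genome_set` and the CLI,
and byte-identical across runs for a fixed config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .gene_panels import MINIMAL_NIF_SET
from .phylogeny import PhyloTree, TreeNode, to_newick
from .sequence_io import GenomeProteome, GenomeSet, SequenceRecord, write_fasta

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_genomes: int = 16
    n_core_families: int = 50
    n_accessory_families: int = 30
    accessory_loss_prob: float = 0.15
    mean_gene_len: int = 300  # codons; hard minimum 60
    tree_birth_rate: float = 1.0
    branch_scale: float = 0.003  # substitutions/site per unit of tree time
    donor_divergence: float = 0.30  # subs/site between the two donor cassettes
    recipient_extra_divergence: float = 0.02
    indel_prob: float = 0.0  # per-branch codon-indel probability (robustness mode)
    # clade label -> donor label or None; None here means the built-in
    # default (first clade -> donorA, second -> donorB, third -> no cassette)
    recipient_assignment: dict[str, str | None] | None = None

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ValueError("n_genomes must be at least 3")
        for p in (self.accessory_loss_prob,):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_gene_len < 60:
            raise ValueError("mean_gene_len must be at least 60 codons")


@dataclass
class TruthBundle:
    """Ground truth emitted alongside the dataset."""

    true_tree: str  # Newick
    core_family_ids: list[str]
    family_content: dict[str, dict[str, str]]  # family -> genome -> protein id
    nif_origin: dict[str, str | None]  # genome -> donor label or None
    clades: dict[str, list[str]]
    donor_panel_files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_tree": self.true_tree,
                "core_family_ids": self.core_family_ids,
                "family_content": self.family_content,
                "nif_origin": self.nif_origin,
                "clades": self.clades,
                "donor_panel_files": self.donor_panel_files,
            },
            indent=2,
            sort_keys=True,
        )


def _yule(n: int, birth_rate: float, rng: np.random.Generator):
    """Yule shape: grow from 2 lineages to n leaves; track the 3 clades."""
    # each alive lineage is a TreeNode whose pending branch length grows
    root = TreeNode()
    alive: list[tuple[TreeNode, float]] = [(TreeNode(), 0.0), (TreeNode(), 0.0)]
    clade_roots: list[TreeNode] | None = None
    root_children = [alive[0][0], alive[1][0]]
    while len(alive) < n:
        wait = rng.exponential(1.0 / (birth_rate * len(alive)))
        alive = [(node, t + wait) for node, t in alive]
        idx = int(rng.integers(len(alive)))
        node, t = alive.pop(idx)
        c1, c2 = TreeNode(), TreeNode()
        node.children = [(c1, 0.0), (c2, 0.0)]
        node._pending = t  # branch length above this internal node
        alive.extend([(c1, 0.0), (c2, 0.0)])
        if clade_roots is None:
            clade_roots = [x for x, _ in alive]  # the 3 lineages alive now
    # one extra waiting time so sister tips are not identical
    wait = rng.exponential(1.0 / (birth_rate * n))
    alive = [(node, t + wait) for node, t in alive]
    for node, t in alive:
        node._pending = t

    def finalize(node: TreeNode) -> None:
        node.children = [(c, getattr(c, "_pending", 0.0)) for c, _ in node.children]
        for c, _ in node.children:
            finalize(c)

    root.children = [(c, 0.0) for c in root_children]
    finalize(root)
    return root, (clade_roots or root_children)


def sample_tree(
    n: int, birth_rate: float, seed: int, branch_scale: float = 1.0
) -> PhyloTree:
    """Yule tree with ``n`` leaves labelled G01..Gnn, lengths scaled."""
    tree, _, _ = _sample_tree_with_clades(n, birth_rate, seed, branch_scale)
    return tree


def _sample_tree_with_clades(
    n: int, birth_rate: float, seed: int, branch_scale: float
):
    if n < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    root, clade_roots = _yule(n, birth_rate, rng)

    def scale(node: TreeNode) -> None:
        node.children = [(c, bl * branch_scale) for c, bl in node.children]
        for c, _ in node.children:
            scale(c)

    scale(root)
    # label leaves in creation-order traversal
    counter = [0]
    width = max(2, len(str(n)))

    def label(node: TreeNode) -> None:
        if node.is_leaf:
            counter[0] += 1
            node.label = f"G{counter[0]:0{width}d}"
        for c, _ in node.children:
            label(c)

    label(root)
    by_key = {}
    for croot in clade_roots:
        leaves = croot.leaves() if not croot.is_leaf else [croot.label]
        by_key[min(leaves)] = (sorted(leaves), croot)
    named = {}
    nodes = {}
    for i, key in enumerate(sorted(by_key)):
        named[f"clade{i + 1}"] = by_key[key][0]
        nodes[f"clade{i + 1}"] = by_key[key][1]
    return PhyloTree(root), named, nodes


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random coding sequence of sense codons (no internal stops)."""
    idx = rng.integers(len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def mutate_cds(seq: str, t: float, rng: np.random.Generator) -> str:
    """One branch of evolution: each site substitutes with probability
    1 - exp(-t), uniformly to one of the 3 alternative bases; any
    substitution that creates a stop codon is redrawn."""
    if t <= 0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(base_codes):
        lookup[b] = i
    state = lookup[codes]
    p = 1.0 - np.exp(-t)
    hit = rng.random(state.size) < p
    shifts = rng.integers(1, 4, size=state.size)
    new_state = state.copy()
    new_state[hit] = (state[hit] + shifts[hit]) % 4
    out = base_codes[new_state]
    result = bytearray(out.tobytes())
    # repair substitutions that created stop codons
    hit_idx = set(np.nonzero(hit)[0].tolist())
    for ci in range(0, len(result) - 2, 3):
        codon = result[ci : ci + 3].decode()
        while codon in _STOPS:
            mutated = [s for s in (ci, ci + 1, ci + 2) if s in hit_idx]
            if not mutated:  # pragma: no cover - root is stop-free
                raise AssertionError("stop codon without substitution")
            s = mutated[int(rng.integers(len(mutated)))]
            orig = lookup[codes[s]]
            alt = (orig + int(rng.integers(1, 4))) % 4
            result[s] = base_codes[alt]
            codon = result[ci : ci + 3].decode()
    return result.decode()


def apply_codon_indel(seq: str, rng: np.random.Generator) -> str:
    """One codon-level indel: delete or duplicate a 1-3 codon block.

    Keeps the sequence in frame and stop-free (duplicating or deleting
    whole sense codons cannot create a stop). Sequences are kept at 60+
    codons so k-mer scores stay meaningful.
    """
    n_codons = len(seq) // 3
    block = int(rng.integers(1, 4))
    if rng.random() < 0.5 and n_codons - block >= 60:  # deletion
        start = int(rng.integers(0, n_codons - block)) * 3
        return seq[:start] + seq[start + 3 * block :]
    start = int(rng.integers(0, max(1, n_codons - block))) * 3  # duplication
    chunk = seq[start : start + 3 * block]
    return seq[:start] + chunk + seq[start:]


def translate_cds(seq: str) -> str:
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    return protein


def evolve_family(
    root_cds: str,
    tree: PhyloTree,
    rate: float,
    rng: np.random.Generator,
    indel_prob: float = 0.0,
) -> dict[str, tuple[str, str]]:
    """Evolve one gene down a tree; returns leaf -> (cds, protein).

    Branch lengths are multiplied by ``rate`` (use rate=1 when the tree
    is already in substitutions/site). ``indel_prob`` is the per-branch
    probability of one codon-level indel (robustness testing only; off
    by default).
    """
    if len(root_cds) % 3:
        raise ValueError("root CDS length must be divisible by 3")
    for i in range(0, len(root_cds) - 3, 3):
        if root_cds[i : i + 3] in _STOPS:
            raise ValueError("root CDS contains an internal stop codon")
    out: dict[str, tuple[str, str]] = {}

    def rec(node: TreeNode, seq: str) -> None:
        if node.is_leaf:
            out[node.label] = (seq, translate_cds(seq))
            return
        for child, bl in node.children:
            evolved = mutate_cds(seq, rate * bl, rng)
            if indel_prob and rng.random() < indel_prob:
                evolved = apply_codon_indel(evolved, rng)
            rec(child, evolved)

    rec(tree.root, root_cds)
    return out


def _accessory_presence(
    tree: PhyloTree, loss_prob: float, rng: np.random.Generator
) -> set[str]:
    """Leaves retaining a family lost independently on each branch."""
    kept: set[str] = set()

    def rec(node: TreeNode, present: bool) -> None:
        if node.is_leaf:
            if present:
                kept.add(node.label)
            return
        for child, _bl in node.children:
            survives = present and rng.random() >= loss_prob
            rec(child, survives)

    rec(tree.root, True)
    return kept


def _gene_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    lo = max(60, int(0.7 * cfg.mean_gene_len))
    hi = int(1.3 * cfg.mean_gene_len)
    return int(rng.integers(lo, hi + 1))


def generate_dataset(config: SimulationConfig, outdir) -> TruthBundle:
    """Write a full synthetic dataset plus its truth to ``outdir``.

    Emits per-genome ``<id>.faa``/``<id>.fna``, ``manifest.tsv``, donor
    panel FASTAs ``donorA.faa``/``donorB.faa`` and ``truth.json``.
    Identical config (seed included) reproduces every file byte for
    byte.
    """
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_roots, s_evo, s_loss, s_cassette = ss.spawn(5)
    tree, clades, clade_nodes = _sample_tree_with_clades(
        config.n_genomes, config.tree_birth_rate, _seed_int(s_tree),
        config.branch_scale,
    )
    genome_ids = sorted(tree.root.leaves())

    assignment = dict(config.recipient_assignment or {})
    if not assignment:
        clade_names = sorted(clades)
        donors = ["donorA", "donorB", None]
        assignment = {
            name: donors[i] if i < len(donors) else None
            for i, name in enumerate(clade_names)
        }
    for clade in assignment:
        if clade not in clades:
            raise ValueError(f"recipient_assignment clade {clade!r} not in tree")
    origin: dict[str, str | None] = {g: None for g in genome_ids}
    for clade, donor in assignment.items():
        for g in clades[clade]:
            origin[g] = donor

    rng_roots = np.random.default_rng(s_roots)
    rng_evo = np.random.default_rng(s_evo)
    rng_loss = np.random.default_rng(s_loss)
    rng_cas = np.random.default_rng(s_cassette)

    n_core, n_acc = config.n_core_families, config.n_accessory_families
    family_ids = [f"core{i:03d}" for i in range(n_core)] + [
        f"acc{i:03d}" for i in range(n_acc)
    ]
    family_content: dict[str, dict[str, str]] = {}
    per_genome: dict[str, list[tuple[str, str, str]]] = {g: [] for g in genome_ids}

    for fam in family_ids:
        root_cds = random_cds(_gene_length(config, rng_roots), rng_roots)
        leaf_seqs = evolve_family(
            root_cds, tree, 1.0, rng_evo, indel_prob=config.indel_prob
        )
        if fam.startswith("acc"):
            kept = _accessory_presence(tree, config.accessory_loss_prob, rng_loss)
        else:
            kept = set(genome_ids)
        content = {}
        for g in genome_ids:
            if g in kept:
                cds, protein = leaf_seqs[g]
                per_genome[g].append((fam, cds, protein))
                content[g] = fam
        family_content[fam] = content

    # nif cassette: one ancestor, two divergent donor copies.  Each donor's
    # cassette is transferred ONCE into the ancestor of its recipient clade
    # (a stem of recipient_extra_divergence from the donor copy) and then
    # descends vertically along that clade's subtree, so cassette sequences
    # carry tree-consistent signal among recipients while remaining
    # donor-attributable.
    donor_seqs: dict[str, dict[str, str]] = {"donorA": {}, "donorB": {}}
    ancestor = {
        m: random_cds(_gene_length(config, rng_cas), rng_cas)
        for m in MINIMAL_NIF_SET
    }
    half = config.donor_divergence / 2.0
    for donor in ("donorA", "donorB"):
        for m in MINIMAL_NIF_SET:
            donor_seqs[donor][m] = mutate_cds(ancestor[m], half, rng_cas)
    recipients_of: dict[str, list[str]] = {}
    for clade, donor in assignment.items():
        if donor is not None:
            recipients_of.setdefault(donor, [])
    for clade, donor in sorted(assignment.items()):
        if donor is None:
            continue
        subtree = PhyloTree(clade_nodes[clade])
        for m in MINIMAL_NIF_SET:
            stem = mutate_cds(
                donor_seqs[donor][m], config.recipient_extra_divergence, rng_cas
            )
            if clade_nodes[clade].is_leaf:
                leaf_seqs = {clade_nodes[clade].label: (stem, translate_cds(stem))}
            else:
                leaf_seqs = evolve_family(stem, subtree, 1.0, rng_cas)
            for g in clades[clade]:
                cds, protein = leaf_seqs[g]
                per_genome[g].append((m, cds, protein))
                family_content.setdefault(f"nif_{donor}_{m}", {})[g] = m

    # write files
    manifest_rows = []
    for g in genome_ids:
        prots = [
            SequenceRecord(name, protein, "protein")
            for name, _cds, protein in per_genome[g]
        ]
        cdss = [
            SequenceRecord(name, cds, "nucleotide")
            for name, cds, _protein in per_genome[g]
        ]
        write_fasta(prots, os.path.join(outdir, f"{g}.faa"))
        write_fasta(cdss, os.path.join(outdir, f"{g}.fna"))
        manifest_rows.append((g, f"{g}.faa", f"{g}.fna"))
    with open(os.path.join(outdir, "manifest.tsv"), "w") as out:
        out.write("genome_id\tproteins_path\tcds_path\n")
        for row in manifest_rows:
            out.write("\t".join(row) + "\n")

    panel_files = {}
    for donor in ("donorA", "donorB"):
        records = [
            SequenceRecord(m, translate_cds(donor_seqs[donor][m]), "protein",
                           f"{donor} reference")
            for m in MINIMAL_NIF_SET
        ]
        fname = f"{donor}.faa"
        write_fasta(records, os.path.join(outdir, fname))
        panel_files[donor] = fname

    # realized core: families actually present in every genome (designated
    # core families, plus any accessory family that escaped loss everywhere)
    realized_core = [
        f for f in family_ids if set(family_content[f]) == set(genome_ids)
    ]
    truth = TruthBundle(
        true_tree=to_newick(tree),
        core_family_ids=realized_core,
        family_content=family_content,
        nif_origin=origin,
        clades=clades,
        donor_panel_files=panel_files,
    )
    with open(os.path.join(outdir, "truth.json"), "w") as out:
        out.write(truth.to_json() + "\n")
    return truth


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def load_truth(path) -> TruthBundle:
    with open(path) as fh:
        data = json.load(fh)
    return TruthBundle(
        true_tree=data["true_tree"],
        core_family_ids=data["core_family_ids"],
        family_content=data["family_content"],
        nif_origin=data["nif_origin"],
        clades=data["clades"],
        donor_panel_files=data["donor_panel_files"],
    )
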