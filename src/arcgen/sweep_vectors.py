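"""Spaced-word proteome vectorization and vector distance matrices.

A whole proteome is summarized as a single fixed-length numeric vector:
spaced words (sub-words read at the '1' positions of a binary mask slid
along every protein) are recorded in a binary occurrence vector over the
20^k word space, which is then compressed by a seeded Gaussian random
projection to p dimensions (default 1369 = 37^2).  Euclidean distances
between such vectors drive the whole-proteome and core-genome phylogenies.

The projection matrix is never materialized in full: at the default
k = 4, p = 1369 it would occupy 1.75 GB.  It is streamed in row blocks
from a single seeded normal stream in fixed row-major order, so the same
(k, p, seed) triple reproduces vectors bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist, squareform

from .sequence_io import GenomeProteome, SequenceRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_CODE = {aa: i for i, aa in enumerate(AA_ORDER)}

DEFAULT_MASK = "11011"
DEFAULT_P = 1369
DEFAULT_SEED = 20210107


@dataclass(frozen=True)
class SpacedWordMask:
    """Binary mask over window positions; '1' marks a care position."""

    pattern: str = DEFAULT_MASK

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - {"0", "1"}:
            raise ValueError(f"mask must be a non-empty 0/1 string: {self.pattern!r}")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise ValueError("mask must begin and end with '1'")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return self.pattern.count("1")

    @property
    def care_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")

    @property
    def n_words(self) -> int:
        return 20 ** self.weight


def enumerate_spaced_words(
    record: SequenceRecord, mask: SpacedWordMask
) -> np.ndarray:
    """Indices of the spaced words of one protein.

    A window starting at each position 0..L-W is read at the mask's care
    positions; residues there are encoded 0..19 in alphabetical order and
    combined base-20 (first care position most significant).  Windows with
    a non-canonical residue (B, J, O, U, X, Z, *) at a care position are
    skipped; non-canonical residues at don't-care positions are harmless.
    Windows never span protein boundaries.
    """
    if record.molecule_type != "protein":
        raise ValueError("spaced words are defined on protein records")
    W = mask.length
    seq = record.residues
    if len(seq) < W:
        return np.empty(0, dtype=np.int64)
    codes = np.array([AA_CODE.get(ch, -1) for ch in seq], dtype=np.int64)
    windows = sliding_window_view(codes, W)[:, list(mask.care_positions)]
    valid = (windows >= 0).all(axis=1)
    k = mask.weight
    weights = 20 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ weights


def occurrence_vector(
    proteome: GenomeProteome, mask: SpacedWordMask, counts: bool = False
) -> np.ndarray:
    """Spaced-word occurrence over the 20^k space for a whole proteome.

    Binary presence/absence by default (order-free and robust to proteome
    size); ``counts=True`` records multiplicities instead.
    """
    occ = np.zeros(mask.n_words, dtype=np.float64)
    for rec in proteome.proteins:
        idx = enumerate_spaced_words(rec, mask)
        if counts:
            np.add.at(occ, idx, 1.0)
        else:
            occ[idx] = 1.0
    return occ


@dataclass(frozen=True)
class ProjectionMatrix:
    """Seeded Gaussian projection from 20^k to p dimensions.

    Entries come from a single standard-normal stream seeded with ``seed``,
    filled row-major and scaled by 1/sqrt(p) (the Johnson-Lindenstrauss
    norm-preserving scaling).  ``row_blocks`` streams the matrix so it is
    never held in memory at once.
    """

    k: int
    p: int = DEFAULT_P
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.k < 1 or self.p < 1:
            raise ValueError("projection dimensions must be positive")

    @property
    def rows(self) -> int:
        return 20 ** self.k

    def row_blocks(self, block_rows: int = 16384):
        """Yield (start_row, block) pairs covering the matrix in order."""
        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(self.p)
        for start in range(0, self.rows, block_rows):
            n = min(block_rows, self.rows - start)
            yield start, rng.standard_normal((n, self.p)) * scale

    def dense(self) -> np.ndarray:
        """Materialize the full matrix (small k only; tests and toys)."""
        return np.concatenate([b for _, b in self.row_blocks()], axis=0)

    def project(self, X: np.ndarray) -> np.ndarray:
        """Compute ``X @ R`` for X of shape (n, 20^k) or (20^k,)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.rows:
            raise ValueError(
                f"projection expects {self.rows} columns, got {X.shape[1]}"
            )
        out = np.zeros((X.shape[0], self.p))
        for start, block in self.row_blocks():
            seg = X[:, start : start + block.shape[0]]
            if seg.any():
                out += seg @ block
        return out


def make_projection(k: int, p: int = DEFAULT_P, seed: int = DEFAULT_SEED) -> ProjectionMatrix:
    return ProjectionMatrix(k=k, p=p, seed=seed)


@dataclass
class SweepVector:
    """Projected proteome vector plus the parameters that produced it."""

    genome_id: str
    values: np.ndarray
    mask_pattern: str
    p: int
    seed: int

    @property
    def params(self) -> tuple[str, int, int]:
        return (self.mask_pattern, self.p, self.seed)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.array_equal(self.D, self.D.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.diagonal(self.D).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.D < 0).any():
            raise ValueError("distance matrix entries must be non-negative")


def vectorize_proteome(
    proteome: GenomeProteome,
    mask: SpacedWordMask,
    proj: ProjectionMatrix,
    counts: bool = False,
) -> SweepVector:
    """Project one proteome's spaced-word occurrence vector."""
    if proj.rows != mask.n_words:
        raise ValueError(
            f"projection rows ({proj.rows}) do not match mask word space "
            f"({mask.n_words})"
        )
    occ = occurrence_vector(proteome, mask, counts=counts)
    values = proj.project(occ)[0]
    return SweepVector(proteome.genome_id, values, mask.pattern, proj.p, proj.seed)


def vectorize_genome_set(
    genomes,
    mask: SpacedWordMask | None = None,
    proj: ProjectionMatrix | None = None,
    counts: bool = False,
) -> list[SweepVector]:
    """Vectorize many proteomes in one streamed pass over the projection."""
    mask = mask or SpacedWordMask()
    proj = proj or make_projection(mask.weight)
    if proj.rows != mask.n_words:
        raise ValueError("projection rows do not match mask word space")
    genomes = list(genomes)
    X = np.stack([occurrence_vector(g, mask, counts=counts) for g in genomes])
    values = proj.project(X)
    return [
        SweepVector(g.genome_id, values[i], mask.pattern, proj.p, proj.seed)
        for i, g in enumerate(genomes)
    ]


def _check_params(vectors: list[SweepVector]) -> None:
    params = {v.params for v in vectors}
    if len(params) > 1:
        raise ValueError(f"vectors built with mixed parameters: {sorted(params)}")


def pairwise_distances(vectors: list[SweepVector]) -> DistanceMatrix:
    """Euclidean distance matrix between vectors sharing one params triple.

    Computed once on the condensed form and mirrored, so the result is
    exactly symmetric.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    _check_params(vectors)
    X = np.stack([v.values for v in vectors])
    D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix([v.genome_id for v in vectors], D)


def kmeans_groups(
    vectors: list[SweepVector], k: int = 4, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means partition of the vectors plus 2-PC coordinates.

    k-means++ initialisation from ``seed`` with 50 restarts keeping the
    best inertia; principal components from exact SVD of the mean-centred
    vector matrix.  Returns (labels, coords) with coords of shape (n, 2).
    """
    from sklearn.cluster import KMeans

    if len(vectors) < k:
        raise ValueError(f"need at least k={k} vectors, got {len(vectors)}")
    _check_params(vectors)
    X = np.stack([v.values for v in vectors])
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    labels = km.fit_predict(X)
    centred = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    coords = U[:, :2] * s[:2]
    return labels, coords


def write_vectors_tsv(vectors: list[SweepVector], path) -> None:
    """Vectors as TSV with a comment header recording mask, p and seed."""
    _check_params(vectors)
    v0 = vectors[0]
    with open(path, "w") as out:
        out.write(f"# mask={v0.mask_pattern} p={v0.p} seed={v0.seed}\n")
        out.write("genome_id\t" + "\t".join(f"v{i}" for i in range(v0.p)) + "\n")
        for v in vectors:
            vals = "\t".join(repr(float(x)) for x in v.values)
            out.write(f"{v.genome_id}\t{vals}\n")


def write_distance_tsv(dm: DistanceMatrix, path, header_comment: str = "") -> None:
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        out.write("\t" + "\t".join(dm.labels) + "\n")
        for lab, row in zip(dm.labels, dm.D):
            out.write(lab + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
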