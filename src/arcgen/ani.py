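"""Average nucleotide identity between genomes, and heat-map matrices.

ANI is estimated alignment-free: the query's concatenated CDS is split
into 1 kb fragments, each fragment's 16-mer containment in the reference
k-mer set is converted to an identity percentage with the Mash distance
transform ``identity = 100 * (1 + (1/k) * ln(2j / (1+j)))``, and ANI is
the mean identity over the fragments that map (containment above a
floor).  The estimate is a deliberately simple fragment/k-mer stand-in
with the same input/output contract and monotone behaviour as dedicated
ANI tools; its absolute values are not interchangeable with theirs.

For heat maps, ANI converts to dissimilarity (100 - ANI) and the strict
lower and upper triangles are each divided by their own mean — the
matrix is generally asymmetric because mapping query fragments against a
reference is directional — then rows and columns are ordered by the
leaf order of an NJ dendrogram of the dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log

import numpy as np

from .sequence_io import GenomeProteome, SequenceRecord


@dataclass(frozen=True)
class AniParams:
    fragment_len: int = 1000
    kmer_len: int = 16
    min_jaccard: float = 0.01

    def __post_init__(self) -> None:
        if self.fragment_len < 3 * self.kmer_len:
            raise ValueError("fragment_len must be at least 3 * kmer_len")


@dataclass
class AniResult:
    ani_pct: float | None
    frags_mapped: int
    frags_total: int


def concat_cds(genome: GenomeProteome) -> SequenceRecord:
    """All CDS of a genome joined, in input order, with no separator."""
    if not genome.cds:
        raise ValueError(f"genome {genome.genome_id!r} has no CDS")
    joined = "".join(rec.residues for rec in genome.cds)
    return SequenceRecord(genome.genome_id, joined, "nucleotide", "concatenated CDS")


def nucleotide_kmers(seq: str, k: int, canonical: bool = False) -> set[str]:
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    if canonical:
        comp = str.maketrans("ACGT", "TGCA")
        kmers = {min(km, km.translate(comp)[::-1]) for km in kmers}
    return kmers


def estimate_identity(
    fragment: str,
    reference_kmers: set[str],
    params: AniParams = AniParams(),
    canonical: bool = False,
) -> float | None:
    """Identity %% of one fragment against a reference k-mer set, or None.

    Containment ``j = |Kmers(frag) & ref| / |Kmers(frag)|``; below
    ``min_jaccard`` the fragment is unmapped (None); otherwise the Mash
    transform maps j to identity, clamped to [0, 100].
    """
    k = params.kmer_len
    if len(fragment) < k:
        return None
    frag_kmers = nucleotide_kmers(fragment, k, canonical=canonical)
    j = len(frag_kmers & reference_kmers) / len(frag_kmers)
    if j < params.min_jaccard:
        return None
    identity = 100.0 * (1.0 + (1.0 / k) * log(2.0 * j / (1.0 + j)))
    return min(max(identity, 0.0), 100.0)


def fragments_of(seq: str, fragment_len: int) -> list[str]:
    """Consecutive windows; the final partial window is kept if >= half."""
    frags = [seq[i : i + fragment_len] for i in range(0, len(seq), fragment_len)]
    if frags and len(frags[-1]) < fragment_len / 2:
        frags.pop()
    return frags


def ani(
    query: GenomeProteome,
    reference: GenomeProteome,
    params: AniParams = AniParams(),
    canonical: bool = False,
) -> AniResult:
    """Directional ANI of query fragments against the reference."""
    q = concat_cds(query).residues
    r = concat_cds(reference).residues
    ref_kmers = nucleotide_kmers(r, params.kmer_len, canonical=canonical)
    frags = fragments_of(q, params.fragment_len)
    identities = []
    for frag in frags:
        ident = estimate_identity(frag, ref_kmers, params, canonical=canonical)
        if ident is not None:
            identities.append(ident)
    if not identities:
        return AniResult(None, 0, len(frags))
    return AniResult(float(np.mean(identities)), len(identities), len(frags))


@dataclass
class AniMatrix:
    """Directional ANI percentages; NaN marks an unmapped pair."""

    labels: list[str]
    A: np.ndarray


def ani_matrix(
    genomes, params: AniParams = AniParams(), canonical: bool = False
) -> AniMatrix:
    """All ordered genome pairs; the diagonal is 100 by definition."""
    genomes = list(genomes)
    labels = [g.genome_id for g in genomes]
    n = len(genomes)
    concats = [concat_cds(g).residues for g in genomes]
    kmer_sets = [
        nucleotide_kmers(c, params.kmer_len, canonical=canonical) for c in concats
    ]
    A = np.full((n, n), np.nan)
    np.fill_diagonal(A, 100.0)
    for qi in range(n):
        frags = fragments_of(concats[qi], params.fragment_len)
        for ri in range(n):
            if qi == ri:
                continue
            identities = [
                ident
                for frag in frags
                if (
                    ident := estimate_identity(
                        frag, kmer_sets[ri], params, canonical=canonical
                    )
                )
                is not None
            ]
            if identities:
                A[qi, ri] = float(np.mean(identities))
    return AniMatrix(labels, A)


@dataclass
class NormalizedDissimilarity:
    """Dissimilarity with each strict triangle scaled to mean 1."""

    labels: list[str]
    M: np.ndarray


def normalize_dissimilarity(am: AniMatrix) -> NormalizedDissimilarity:
    """100 - ANI with triangular mean-normalisation.

    Unmapped (NaN) entries become their triangle's maximum dissimilarity
    so heat maps stay total; then the strict lower and strict upper
    triangles are each divided by their own mean, and the diagonal is
    set to 0.  Applying the normalisation twice is the identity.
    """
    D = 100.0 - np.asarray(am.A, dtype=float)
    n = D.shape[0]
    il = np.tril_indices(n, -1)
    iu = np.triu_indices(n, 1)
    for idx in (il, iu):
        vals = D[idx]
        if np.isnan(vals).any():
            fill = np.nanmax(vals) if not np.isnan(vals).all() else 0.0
            vals = np.where(np.isnan(vals), fill, vals)
        mean = vals.mean() if vals.size else 0.0
        if mean > 0:
            vals = vals / mean
        else:
            warnings.warn("all-zero triangle: mean-normalisation skipped")
        D[idx] = vals
    np.fill_diagonal(D, 0.0)
    return NormalizedDissimilarity(list(am.labels), D)


def symmetrized(nd: NormalizedDissimilarity):
    """(M + M^T) / 2 as a DistanceMatrix, for NJ ordering of heat maps."""
    from .sweep_vectors import DistanceMatrix

    S = 0.5 * (nd.M + nd.M.T)
    S = np.maximum(S, 0.0)
    np.fill_diagonal(S, 0.0)
    return DistanceMatrix(list(nd.labels), S)


def heatmap_matrix(nd: NormalizedDissimilarity, order: list[str]) -> "pd.DataFrame":
    """Rows/columns permuted to a dendrogram leaf order."""
    import pandas as pd

    if sorted(order) != sorted(nd.labels):
        raise ValueError("order is not a permutation of the matrix labels")
    df = pd.DataFrame(nd.M, index=nd.labels, columns=nd.labels)
    return df.loc[order, order]


def write_ani_tsv(am: AniMatrix, path, header_comment: str = "") -> None:
    import pandas as pd

    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        pd.DataFrame(am.A, index=am.labels, columns=am.labels).to_csv(out, sep="\t")


def write_matrix_tsv(df, path, header_comment: str = "") -> None:
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        df.to_csv(out, sep="\t")
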