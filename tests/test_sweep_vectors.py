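import numpy as np
import pytest

from arcgen.sequence_io import SequenceRecord
from arcgen.sweep_vectors import (
    DistanceMatrix,
    SpacedWordMask,
    SweepVector,
    enumerate_spaced_words,
    kmeans_groups,
    make_projection,
    occurrence_vector,
    pairwise_distances,
    vectorize_proteome,
)
from conftest import make_genome


def prot(seq, pid="p1"):
    return SequenceRecord(pid, seq, "protein")


class TestSpacedWordMask:
    def test_default_mask_shape(self):
        m = SpacedWordMask()
        assert (m.pattern, m.length, m.weight) == ("11011", 5, 4)
        assert m.care_positions == (0, 1, 3, 4)

    @pytest.mark.parametrize("bad", ["0110", "10", "", "12011"])
    def test_invalid_masks_rejected(self, bad):
        with pytest.raises(ValueError):
            SpacedWordMask(bad)


class TestEnumerateSpacedWords:
    def test_hand_encoded_index(self):
        # care residues A,C,E,F -> 0*8000 + 1*400 + 3*20 + 4 = 464
        idx = enumerate_spaced_words(prot("ACDEF"), SpacedWordMask())
        assert idx.tolist() == [464]

    def test_sequence_shorter_than_window_is_empty(self):
        assert enumerate_spaced_words(prot("MKV"), SpacedWordMask()).size == 0

    def test_non_canonical_at_dont_care_position_is_kept(self):
        # X sits at the '0' position of 11011, so the word is unchanged
        idx = enumerate_spaced_words(prot("ACXEF"), SpacedWordMask())
        assert idx.tolist() == [464]

    def test_non_canonical_at_care_position_skips_window(self):
        assert enumerate_spaced_words(prot("XCDEF"), SpacedWordMask()).size == 0

    def test_sliding_window_count(self):
        idx = enumerate_spaced_words(prot("ACDEFGHIK"), SpacedWordMask())
        assert idx.size == 5  # L - W + 1


class TestProjection:
    def test_determinism_bit_identical(self):
        a = make_projection(2, 37, 42).dense()
        b = make_projection(2, 37, 42).dense()
        assert np.array_equal(a, b)

    def test_default_output_width_is_1369(self):
        assert make_projection(4).p == 1369

    def test_jl_norm_preservation(self):
        """E[|R^T x|^2] ~ |x|^2 under the 1/sqrt(p) scaling."""
        rng = np.random.default_rng(0)
        proj = make_projection(2, 400, 7)
        ratios = []
        for _ in range(100):
            x = (rng.random(400) < 0.1).astype(float)
            y = proj.project(x)[0]
            ratios.append(np.sum(y**2) / np.sum(x**2))
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            make_projection(0, 10, 1)
        with pytest.raises(ValueError):
            make_projection(2, 0, 1)

    def test_chunked_projection_matches_dense(self):
        proj = make_projection(2, 50, 3)
        x = np.arange(400, dtype=float)
        assert np.allclose(proj.project(x)[0], x @ proj.dense(), atol=1e-9)


class TestVectorize:
    mask = SpacedWordMask("101")  # k=2, 400-dim word space: fast

    def test_vector_length_matches_projection(self):
        g = make_genome("g1", {"p1": "ACDEFGHIK"})
        v = vectorize_proteome(g, self.mask, make_projection(2, 1369, 1))
        assert v.values.shape == (1369,)

    def test_protein_order_and_duplication_invariance(self):
        proj = make_projection(2, 64, 1)
        a = make_genome("a", {"p1": "ACDEFG", "p2": "MKVLIW"})
        b = make_genome("b", {"x": "MKVLIW", "y": "ACDEFG", "z": "ACDEFG"})
        va = vectorize_proteome(a, self.mask, proj)
        vb = vectorize_proteome(b, self.mask, proj)
        assert np.allclose(va.values, vb.values, atol=1e-12)

    def test_no_valid_windows_gives_zero_vector(self):
        g = make_genome("g1", {"p1": "MK"})
        v = vectorize_proteome(g, self.mask, make_projection(2, 16, 1))
        assert np.all(v.values == 0)

    def test_mask_projection_mismatch_rejected(self):
        g = make_genome("g1", {"p1": "ACDEF"})
        with pytest.raises(ValueError):
            vectorize_proteome(g, SpacedWordMask("11011"), make_projection(2, 16, 1))


class TestDistances:
    def vec(self, gid, values):
        return SweepVector(gid, np.asarray(values, float), "101", len(values), 0)

    def test_three_four_five(self):
        dm = pairwise_distances([self.vec("a", [0, 0]), self.vec("b", [3, 4])])
        assert dm.D[0, 1] == pytest.approx(5.0)

    def test_identical_vectors_distance_zero_and_exact_symmetry(self):
        vs = [self.vec("a", [1, 2]), self.vec("b", [1, 2]), self.vec("c", [0, 1])]
        dm = pairwise_distances(vs)
        assert dm.D[0, 1] == 0
        assert np.array_equal(dm.D, dm.D.T)
        assert np.all(np.diag(dm.D) == 0)

    def test_mixed_params_refused(self):
        a = self.vec("a", [1, 2])
        b = SweepVector("b", np.array([1.0, 2.0]), "101", 2, 99)
        with pytest.raises(ValueError, match="mixed"):
            pairwise_distances([a, b])

    def test_distance_matrix_validates_symmetry(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestKmeans:
    def blobs(self, rng, k=4, per=20, sep=10.0):
        vecs, labels = [], []
        for ci in range(k):
            centre = rng.normal(scale=sep, size=5)
            for j in range(per):
                vals = centre + rng.normal(scale=1.0, size=5)
                vecs.append(SweepVector(f"g{ci}_{j}", vals, "101", 5, 0))
                labels.append(ci)
        return vecs, labels

    def test_recovers_separated_blobs_exactly(self):
        rng = np.random.default_rng(5)
        vecs, true = self.blobs(rng)
        labels, coords = kmeans_groups(vecs, k=4, seed=0)
        # same partition up to label permutation
        mapping = {}
        for est, t in zip(labels, true):
            mapping.setdefault(est, t)
            assert mapping[est] == t
        assert len(set(mapping.values())) == 4
        assert coords.shape == (len(vecs), 2)

    def test_k1_inertia_is_total_centred_ss(self):
        rng = np.random.default_rng(2)
        vecs, _ = self.blobs(rng, k=2, per=5)
        labels, coords = kmeans_groups(vecs, k=1, seed=0)
        assert set(labels) == {0}

    def test_duplicate_points_share_labels(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vecs = [SweepVector(f"g{i}", vals.copy(), "101", 5, 0) for i in range(3)]
        far = [SweepVector(f"h{i}", vals + 50, "101", 5, 0) for i in range(3)]
        labels, _ = kmeans_groups(vecs + far, k=2, seed=1)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_fewer_vectors_than_k_rejected(self):
        vecs = [SweepVector("a", np.ones(3), "101", 3, 0)]
        with pytest.raises(ValueError):
            kmeans_groups(vecs, k=2, seed=0)


def test_distance_grows_with_divergence():
    """Vector distance between two evolved proteomes rises monotonically
    (Spearman rho > 0.9) with substitutions per site over 0-0.4."""
    from scipy.stats import spearmanr

    from arcgen.phylogeny import PhyloTree, TreeNode
    from arcgen.sequence_io import GenomeProteome
    from arcgen.sweep_vectors import vectorize_genome_set
    from arcgen.synthetic_data import evolve_family, random_cds

    mask = SpacedWordMask("1011")  # k=3: sparse occupancy at test scale
    proj = make_projection(3, 1369, 20210107)
    rates = [0.0, 0.05, 0.1, 0.2, 0.3, 0.4]
    rhos = []
    for rep in range(3):
        rng = np.random.default_rng(100 + rep)
        roots = [random_cds(200, rng) for _ in range(30)]
        dists = []
        for rate in rates:
            tree = PhyloTree(
                TreeNode(children=[
                    (TreeNode(label="a"), rate / 2), (TreeNode(label="b"), rate / 2),
                ])
            )
            prots = {"a": [], "b": []}
            for i, root in enumerate(roots):
                leafs = evolve_family(root, tree, 1.0, rng)
                for leaf in ("a", "b"):
                    prots[leaf].append(
                        SequenceRecord(f"f{i}", leafs[leaf][1], "protein")
                    )
            va, vb = vectorize_genome_set(
                [GenomeProteome("a", prots["a"]), GenomeProteome("b", prots["b"])],
                mask,
                proj,
            )
            dists.append(float(np.linalg.norm(va.values - vb.values)))
        rhos.append(spearmanr(rates, dists).statistic)
    assert min(rhos) > 0.9
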