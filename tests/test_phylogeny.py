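import itertools

import numpy as np
import pytest

from arcgen.phylogeny import (
    PhyloTree,
    TreeNode,
    leaf_order,
    neighbor_joining,
    read_newick,
    robinson_foulds,
    to_newick,
    tree_distances,
    write_newick,
)
from arcgen.sweep_vectors import DistanceMatrix


def dm(labels, rows):
    return DistanceMatrix(labels, np.array(rows, dtype=float))


def random_additive_matrix(n, rng):
    """Random binary tree with positive branch lengths -> (matrix, tree)."""
    nodes = [TreeNode(label=f"t{i:02d}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = TreeNode(children=[
            (nodes[i], rng.uniform(0.1, 1.0)),
            (nodes[j], rng.uniform(0.1, 1.0)),
        ])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [b]
    root = TreeNode(children=[(x, rng.uniform(0.1, 1.0)) for x in nodes])
    tree = PhyloTree(root)
    return tree_distances(tree), tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        t = neighbor_joining(dm(list("ABC"), [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
        branches = {c.label: bl for c, bl in t.root.children}
        assert branches["A"] == pytest.approx(0.0, abs=1e-9)
        assert branches["B"] == pytest.approx(2.0, abs=1e-9)
        assert branches["C"] == pytest.approx(4.0, abs=1e-9)

    def test_four_taxon_topology_by_least_squares_oracle(self):
        """NJ agrees with brute-force least squares over the 3 topologies."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            D, true_tree = random_additive_matrix(4, rng)
            labels = D.labels
            # oracle: score each unrooted quartet topology by OLS fit
            def quartet_tree(pair):
                (a, b), (c, d) = pair, tuple(x for x in labels if x not in pair)
                return (a, b, c, d)

            def ols_error(quartet):
                a, b, c, d = quartet
                i = {lab: labels.index(lab) for lab in labels}
                # four-point condition residual
                s1 = D.D[i[a], i[b]] + D.D[i[c], i[d]]
                s2 = D.D[i[a], i[c]] + D.D[i[b], i[d]]
                s3 = D.D[i[a], i[d]] + D.D[i[b], i[c]]
                return s1 - min(s1, s2, s3)

            best = min(
                (tuple(sorted(p)) for p in itertools.combinations(labels, 2)),
                key=lambda p: ols_error(quartet_tree(p)),
            )
            est = neighbor_joining(D)
            split = {
                frozenset(side)
                for side in _nontrivial_sides(est)
            }
            assert frozenset(best) in split or frozenset(
                set(labels) - set(best)
            ) in split

    def test_consistent_on_additive_matrices(self):
        """NJ recovers the generating topology (RF=0) on 100 random
        additive matrices with n <= 12."""
        rng = np.random.default_rng(42)
        for rep in range(100):
            n = int(rng.integers(4, 13))
            D, tree = random_additive_matrix(n, rng)
            est = neighbor_joining(D)
            assert robinson_foulds(est, tree) == 0

    def test_path_lengths_reproduce_additive_input(self):
        rng = np.random.default_rng(1)
        D, _ = random_additive_matrix(8, rng)
        est = neighbor_joining(D)
        D2 = tree_distances(est)
        assert D2.labels == D.labels
        assert np.allclose(D2.D, D.D, atol=1e-9)

    def test_tie_handling_is_deterministic(self):
        M = [
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ]
        outs = {to_newick(neighbor_joining(dm(list("ABCD"), M))) for _ in range(5)}
        assert len(outs) == 1

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        D, tree = random_additive_matrix(7, rng)
        perm = list(rng.permutation(len(D.labels)))
        D2 = DistanceMatrix(
            [D.labels[i] for i in perm], D.D[np.ix_(perm, perm)]
        )
        assert to_newick(neighbor_joining(D)) == to_newick(neighbor_joining(D2))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm(["a", "b"], [[0, 1], [1, 0]]))


def _nontrivial_sides(tree):
    all_leaves = set(tree.root.leaves())
    sides = []

    def rec(node):
        if node.is_leaf:
            return {node.label}
        below = set()
        for c, _ in node.children:
            below |= rec(c)
        if 1 < len(below) < len(all_leaves) - 1:
            sides.append(below)
        return below

    rec(tree.root)
    return sides


class TestNewick:
    def test_three_leaf_star_serialization(self):
        t = neighbor_joining(dm(list("ABC"), [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
        assert to_newick(t) == "(A:0,B:2,C:4);"

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(4)
        D, _ = random_additive_matrix(9, rng)
        t = neighbor_joining(D)
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(str(path))
        assert robinson_foulds(t, back) == 0
        assert np.allclose(
            tree_distances(back).D, tree_distances(t).D, rtol=1e-4
        )

    def test_relabelling_only_permutes_labels(self):
        t1 = neighbor_joining(dm(list("ABC"), [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
        t2 = neighbor_joining(dm(list("XYZ"), [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
        assert to_newick(t2) == to_newick(t1).replace("A", "X").replace(
            "B", "Y"
        ).replace("C", "Z")


class TestRobinsonFoulds:
    def t(self, newick):
        return read_newick(newick)

    def test_identical_trees_distance_zero(self):
        a = self.t("((A:1,B:1):1,(C:1,D:1):1);")
        assert robinson_foulds(a, a) == 0

    def test_conflicting_quartets_distance_two(self):
        a = self.t("((A:1,B:1):1,(C:1,D:1):1);")
        b = self.t("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(a, b) == 2

    def test_symmetry_on_random_trees(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            _, t1 = random_additive_matrix(8, rng)
            _, t2 = random_additive_matrix(8, rng)
            # relabel to the same leaf set
            assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1)

    def test_leaf_set_mismatch_rejected(self):
        a = self.t("((A:1,B:1):1,(C:1,D:1):1);")
        b = self.t("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError):
            robinson_foulds(a, b)

    def test_agrees_with_dendropy_oracle(self):
        import dendropy

        rng = np.random.default_rng(21)
        for _ in range(5):
            _, t1 = random_additive_matrix(10, rng)
            _, t2 = random_additive_matrix(10, rng)
            n1, n2 = to_newick(t1), to_newick(t2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert robinson_foulds(t1, t2) == expected


class TestLeafOrder:
    def test_three_leaf_ladder_order(self):
        t = neighbor_joining(dm(list("ABC"), [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
        assert leaf_order(t) == ["A", "B", "C"]

    def test_order_is_permutation_and_stable(self):
        rng = np.random.default_rng(8)
        D, _ = random_additive_matrix(10, rng)
        t = neighbor_joining(D)
        order = leaf_order(t)
        assert sorted(order) == sorted(D.labels)
        assert leaf_order(t) == order
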