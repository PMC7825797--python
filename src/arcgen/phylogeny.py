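"""Neighbour-joining trees, Newick serialization and tree comparison.

Classical Saitou-Nei neighbour joining over any labelled symmetric
distance matrix, with two behaviours pinned for reproducibility that
textbook statements leave open: ties in the Q criterion resolve to the
lexicographically smallest pair of node labels (an internal node carries
the smallest leaf label of its subtree), and a negative branch length is
clamped to zero with the deficit transferred to its sister branch so
path lengths are preserved.  Trees ladderize deterministically (children
by subtree leaf count, ties by smallest leaf label), which fixes both
the Newick string and the heat-map row order derived from ``leaf_order``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sweep_vectors import DistanceMatrix


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry a label."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree serialized from a (possibly trifurcating) anchor node."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def ladderize(self) -> None:
        """Order children by (subtree leaf count, smallest leaf label)."""

        def key(child_edge):
            child, _ = child_edge
            lv = child.leaves()
            return (len(lv), min(lv))

        def rec(node: TreeNode) -> None:
            for child, _ in node.children:
                rec(child)
            node.children.sort(key=key)

        rec(self.root)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ tree from a symmetric zero-diagonal matrix (n >= 3).

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (r = row sums), with branch
    lengths from the standard two-point formulas; ends in a central
    trifurcation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = dm.D.copy()
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    # comparison label: smallest leaf label under the node
    tags = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    pair_tag = tuple(sorted((tags[active[a]], tags[active[b]])))
                    if best is None or pair_tag < best[0]:
                        best = (pair_tag, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        bi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        bj = dij - bi
        # clamp negatives, moving the deficit to the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        # distances from the new node to the remaining ones
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        idx_new = D.shape[0] - 1
        D[idx_new, active] = new_row
        D[active, idx_new] = new_row
        D[idx_new, idx_new] = 0.0
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [x for x in active if x not in (i, j)] + [idx_new]

    # final trifurcation via the three-point formulas
    i, j, k = active
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    center = TreeNode(
        children=[
            (nodes[i], max(bi, 0.0)),
            (nodes[j], max(bj, 0.0)),
            (nodes[k], max(bk, 0.0)),
        ]
    )
    tree = PhyloTree(center)
    tree.ladderize()
    return tree


def _newick(node: TreeNode, length: float | None) -> str:
    if node.is_leaf:
        body = node.label
    else:
        body = "(" + ",".join(_newick(c, bl) for c, bl in node.children) + ")"
    if length is None:
        return body
    return f"{body}:{length:.6g}"


def to_newick(t: PhyloTree) -> str:
    """Deterministic Newick string (ladderized, 6 significant digits)."""
    t.ladderize()
    return _newick(t.root, None) + ";"


def write_newick(t: PhyloTree, path) -> None:
    with open(path, "w") as out:
        out.write(to_newick(t) + "\n")


def read_newick(source: str) -> PhyloTree:
    """Parse a Newick string or file path into a :class:`PhyloTree`."""
    import dendropy

    if "(" in source:
        dt = dendropy.Tree.get(data=source, schema="newick")
    else:
        dt = dendropy.Tree.get(path=source, schema="newick")

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(label=dnode.taxon.label.replace(" ", "_"))
        node = TreeNode()
        for child in dnode.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            node.children.append((convert(child), float(bl)))
        return node

    return PhyloTree(convert(dt.seed_node))


def _bipartitions(t: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the overall smallest leaf label."""
    all_leaves = frozenset(t.root.leaves())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def rec(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(rec(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
        return below

    rec(t.root)
    return splits


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Count of non-trivial bipartitions present in exactly one tree."""
    l1, l2 = set(t1.root.leaves()), set(t2.root.leaves())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def leaf_order(t: PhyloTree) -> list[str]:
    """Left-to-right leaf order of the ladderized tree (heat-map order)."""
    t.ladderize()
    return t.root.leaves()


def tree_distances(t: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    labels = sorted(t.root.leaves())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def rec(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {index[node.label]: 0.0}
        merged: dict[int, float] = {}
        for child, bl in node.children:
            sub = {k: v + bl for k, v in rec(child).items()}
            for k1, v1 in merged.items():
                for k2, v2 in sub.items():
                    D[k1, k2] = D[k2, k1] = v1 + v2
            merged.update(sub)
        return merged

    rec(t.root)
    return DistanceMatrix(labels, D)
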