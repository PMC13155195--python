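"""Rooted full binary trees over taxa and count aggregation.

The tree plays two roles: it defines the sequential-binomial decomposition of
the multinomial sampling model (counts split left/right at every interior
node) and it fixes the coordinate system — one log-odds per interior node —
in which the latent Gaussian lives.  Only the topology is used; branch
lengths are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "BinaryTaxonomyTree",
    "aggregate_node_counts",
    "NodeCountTable",
    "random_binary_tree",
]


def _ladderize(nested):
    """Resolve multifurcations deterministically: fold the first two children
    into a new interior node until exactly two remain (left-ladder)."""
    if isinstance(nested, str):
        return nested
    items = [_ladderize(c) for c in nested]
    if len(items) == 1:  # collapse unary nodes
        return items[0]
    while len(items) > 2:
        items = [(items[0], items[1]), *items[2:]]
    return (items[0], items[1])


@dataclass
class BinaryTaxonomyTree:
    """A rooted full binary tree over K taxa.

    Interior nodes are indexed 0..d-1 (d = K-1) in DFS preorder with the
    left child visited first; the root has index 0.  Leaves are indexed
    0..K-1 in the order they are encountered by the same DFS, and
    ``leaf_labels`` records their names.  All model vectors over interior
    nodes use this node order; all compositions use this leaf order.

    ``node_mask[i, j]`` is True iff leaf j descends from interior node i,
    and ``left_mask[i, j]`` iff leaf j descends from its left child.  The
    left child is the first child in the stored (Newick) child order.
    """

    leaf_labels: list[str]
    node_mask: np.ndarray  # (d, K) bool
    left_mask: np.ndarray  # (d, K) bool
    children: list[tuple[tuple[str, int], tuple[str, int]]] = field(repr=False)

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #

    @classmethod
    def from_nested(cls, nested) -> "BinaryTaxonomyTree":
        """Build from nested tuples/lists of leaf-label strings,
        e.g. ``(("u1","u2"),("u3","u4"))``.  Multifurcations are
        left-ladderized."""
        nested = _ladderize(nested)
        if isinstance(nested, str):
            raise ValueError("tree must have at least 2 leaves")
        leaf_labels: list[str] = []
        children: list = []

        def visit(t):
            if isinstance(t, str):
                leaf_labels.append(t)
                return ("leaf", len(leaf_labels) - 1)
            idx = len(children)
            children.append(None)
            left = visit(t[0])
            right = visit(t[1])
            children[idx] = (left, right)
            return ("node", idx)

        visit(nested)
        if len(set(leaf_labels)) != len(leaf_labels):
            dups = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dups}")
        K = len(leaf_labels)
        d = K - 1
        node_mask = np.zeros((d, K), dtype=bool)
        left_mask = np.zeros((d, K), dtype=bool)

        def fill(ref) -> np.ndarray:
            kind, idx = ref
            if kind == "leaf":
                m = np.zeros(K, dtype=bool)
                m[idx] = True
                return m
            l, r = children[idx]
            ml = fill(l)
            mr = fill(r)
            left_mask[idx] = ml
            node_mask[idx] = ml | mr
            return node_mask[idx]

        fill(("node", 0))
        return cls(leaf_labels=leaf_labels, node_mask=node_mask,
                   left_mask=left_mask, children=children)

    @classmethod
    def from_newick(cls, source: str) -> "BinaryTaxonomyTree":
        """Parse a Newick string (or path ending in .nwk/.newick/.tree).

        Branch lengths are discarded; multifurcations are left-ladderized in
        the stored child order, so re-reading the same string always yields
        the same node indexing.
        """
        text = source
        if source.strip().endswith((".nwk", ".newick", ".tree")):
            with open(source) as fh:
                text = fh.read()
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises its own hierarchy
            raise ValueError(f"failed to parse Newick input: {exc}") from exc

        def to_nested(node):
            ch = node.child_nodes()
            if not ch:
                label = node.taxon.label if node.taxon else node.label
                if label is None:
                    raise ValueError("unlabeled leaf in Newick input")
                return str(label)
            return [to_nested(c) for c in ch]

        return cls.from_nested(to_nested(dtree.seed_node))

    # ------------------------------------------------------------------ #
    # basic properties
    # ------------------------------------------------------------------ #

    @property
    def K(self) -> int:
        return len(self.leaf_labels)

    @property
    def d(self) -> int:
        return self.K - 1

    @property
    def right_mask(self) -> np.ndarray:
        return self.node_mask & ~self.left_mask

    def node_name(self, i: int) -> str:
        """Stable interior-node label: DFS index plus the lexicographically
        smallest descendant leaf."""
        leaves = [self.leaf_labels[j] for j in np.flatnonzero(self.node_mask[i])]
        return f"n{i}|{min(leaves)}"

    def to_newick(self) -> str:
        def render(ref):
            kind, idx = ref
            if kind == "leaf":
                return self.leaf_labels[idx]
            l, r = self.children[idx]
            return f"({render(l)},{render(r)})"
        return render(("node", 0)) + ";"

    # ------------------------------------------------------------------ #
    # ilr basis
    # ------------------------------------------------------------------ #

    def ilr_basis(self) -> np.ndarray:
        """The (d, K) sequential-binary-partition contrast matrix V.

        Row A carries +sqrt(r/(l(l+r))) on left-descendant leaves and
        -sqrt(l/(r(l+r))) on right-descendant leaves, where l = |A_l| and
        r = |A_r|; rows are orthonormal and orthogonal to the all-ones
        vector, so eta = V clr(p) and clr = V^T eta.
        """
        L = self.left_mask
        R = self.right_mask
        l = L.sum(axis=1).astype(float)
        r = R.sum(axis=1).astype(float)
        V = (L * np.sqrt(r / (l * (l + r)))[:, None]
             - R * np.sqrt(l / (r * (l + r)))[:, None])
        return V


@dataclass
class NodeCountTable:
    """Per-sample subtree totals for every interior node.

    ``y[i, A]`` is the total count in sample i over the leaves descending
    from node A; ``y_left[i, A]`` the part descending from its left child.
    ``totals`` is the per-sample sequencing depth (the root total).
    """

    y: np.ndarray        # (n, d) int
    y_left: np.ndarray   # (n, d) int
    totals: np.ndarray   # (n,) int

    @property
    def kappa(self) -> np.ndarray:
        """The Polya-Gamma natural-parameter offset y_left - y/2."""
        return self.y_left - self.y / 2.0


def aggregate_node_counts(
    X: np.ndarray,
    tree: BinaryTaxonomyTree,
    labels: list[str] | None = None,
) -> NodeCountTable:
    """Aggregate a (n, K) taxon count matrix down the tree.

    If ``labels`` is given, columns of X are matched to tree leaves by
    label (order-independent); otherwise columns are assumed to already be
    in tree leaf order.
    """
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    if np.any(X < 0) or not np.issubdtype(X.dtype, np.integer) and np.any(X != np.floor(X)):
        raise ValueError("counts must be non-negative integers")
    if labels is not None:
        missing = [t for t in tree.leaf_labels if t not in labels]
        extra = [t for t in labels if t not in tree.leaf_labels]
        if missing or extra:
            raise ValueError(
                f"count table / tree leaf mismatch: missing from table {missing}, "
                f"absent from tree {extra}"
            )
        order = [labels.index(t) for t in tree.leaf_labels]
        X = X[:, order]
    elif X.shape[1] != tree.K:
        raise ValueError(f"X has {X.shape[1]} columns but tree has {tree.K} leaves")
    X = X.astype(np.int64)
    y = X @ tree.node_mask.T.astype(np.int64)
    y_left = X @ tree.left_mask.T.astype(np.int64)
    return NodeCountTable(y=y, y_left=y_left, totals=X.sum(axis=1))


def random_binary_tree(K: int, seed=None, prefix: str = "t") -> BinaryTaxonomyTree:
    """Random rooted full binary tree over K labeled leaves, grown by
    repeatedly joining two uniformly chosen subtrees (random coalescent
    topology).  Deterministic given the seed."""
    if K < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    forest: list = [f"{prefix}{j + 1}" for j in range(K)]
    while len(forest) > 1:
        i, j = sorted(rng.choice(len(forest), size=2, replace=False))
        b = forest.pop(j)
        a = forest.pop(i)
        forest.append((a, b))
    return BinaryTaxonomyTree.from_nested(forest[0])


def balanced_tree(K: int, prefix: str = "t") -> BinaryTaxonomyTree:
    """Balanced-as-possible tree over K leaves (left half vs right half,
    recursively)."""
    labels = [f"{prefix}{j + 1}" for j in range(K)]

    def split(lo, hi):
        if hi - lo == 1:
            return labels[lo]
        mid = (lo + hi + 1) // 2
        return (split(lo, mid), split(mid, hi))

    return BinaryTaxonomyTree.from_nested(split(0, K))
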