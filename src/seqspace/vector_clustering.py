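"""Hierarchy-consistent clustering of embedding vectors.

Two routes produce a merge tree over sequences:

* **Bisecting K-means** (divisive): start with one cluster holding all
  sequences and repeatedly 2-means-split the leaf with the largest SSE
  (sum of squared Euclidean distances to the leaf centroid) until ``k_max``
  leaves exist.  The full split tree is retained; the branch length from a
  parent to a child is SSE(parent) - SSE(child).  Off-the-shelf bisecting
  K-means re-run at each K does not produce nested partitions across K;
  here the retained tree is converted once into a single-linkage merge
  structure (item distance = branch-length path between leaves) and then
  flattened at any K with maxclust semantics, which guarantees that finer
  partitions refine coarser ones.

* **Agglomerative** (WPGMA over cosine distances): the standard weighted
  linkage, emitted both as a linkage matrix and as a rooted tree with
  branch lengths equal to merge-height differences.

Both trees round-trip through Newick via :mod:`seqspace.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from sklearn.cluster import KMeans

from .components import Partition
from .embedding import EmbeddingMatrix
from .errors import CoverageError, DimensionError, MemoryBudgetError

#: conventional 2-means settings used at every split (seeded per split)
KMEANS_N_INIT = 10
KMEANS_TOL = 1e-6
KMEANS_MAX_ITER = 300

AGGLOM_MAX_ITEMS = 50_000


def _sse(X: np.ndarray, idx: np.ndarray) -> float:
    sub = X[idx]
    centroid = sub.mean(axis=0)
    return float(((sub - centroid) ** 2).sum())


@dataclass(eq=False)
class BisectNode:
    """A node of the bisecting split tree: member indices, SSE, 0 or 2 children."""

    indices: np.ndarray
    sse: float
    left: "BisectNode | None" = None
    right: "BisectNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def min_index(self) -> int:
        return int(self.indices.min())


@dataclass
class BisectingTree:
    """Retained bisecting K-means tree over an embedding matrix."""

    root: BisectNode
    ids: list[str]

    def leaves(self) -> list[BisectNode]:
        """Leaves ordered by smallest member index (the canonical item order)."""
        out: list[BisectNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        out.sort(key=lambda n: n.min_index)
        return out

    def leaf_partition(self) -> Partition:
        """The partition formed by the current leaves (canonical labels)."""
        assignment: dict[str, str] = {}
        for leaf in self.leaves():
            members = [self.ids[i] for i in leaf.indices]
            label = min(members)
            for sid in members:
                assignment[sid] = label
        return Partition(level=f"K:{self.n_leaves}", assignment=assignment)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


def bisecting_kmeans(vectors: EmbeddingMatrix, k_max: int, seed: int = 0) -> BisectingTree:
    """Divisive 2-means clustering retaining the full split tree.

    At each step the leaf with the largest SSE is split (ties broken by the
    leaf whose smallest member index is smallest, for determinism); each
    split runs seeded k-means++ with ``KMEANS_N_INIT`` restarts.  Stops at
    ``k_max`` leaves (or earlier if every leaf is a singleton).
    """
    n = vectors.n
    if not (2 <= k_max <= n):
        raise DimensionError(f"k_max={k_max} must be within [2, n={n}]")
    X = vectors.X
    root = BisectNode(indices=np.arange(n), sse=_sse(X, np.arange(n)))
    leaves = [root]
    split_count = 0
    while len(leaves) < k_max:
        candidates = [l for l in leaves if len(l.indices) >= 2]
        if not candidates:
            break
        target = max(candidates, key=lambda l: (l.sse, -l.min_index))
        rs = (seed * 1_000_003 + split_count) % (2**31 - 1)
        split_count += 1
        sub = X[target.indices]
        if np.allclose(sub, sub[0]):
            # all points identical: SSE split is meaningless; halve by index
            half = len(target.indices) // 2
            left_idx = target.indices[:half] if half else target.indices[:1]
            right_idx = target.indices[len(left_idx):]
        else:
            km = KMeans(n_clusters=2, n_init=KMEANS_N_INIT, tol=KMEANS_TOL,
                        max_iter=KMEANS_MAX_ITER, random_state=rs)
            labels = km.fit_predict(sub)
            left_idx = target.indices[labels == 0]
            right_idx = target.indices[labels == 1]
            if len(left_idx) == 0 or len(right_idx) == 0:
                half = len(target.indices) // 2
                left_idx = target.indices[:half]
                right_idx = target.indices[half:]
        left = BisectNode(indices=left_idx, sse=_sse(X, left_idx))
        right = BisectNode(indices=right_idx, sse=_sse(X, right_idx))
        if right.min_index < left.min_index:
            left, right = right, left
        target.left, target.right = left, right
        leaves.remove(target)
        leaves.extend([left, right])
    return BisectingTree(root=root, ids=list(vectors.ids))


@dataclass
class MergeLinkage:
    """A SciPy-style linkage over labelled items (each item = a set of sequence ids)."""

    Z: np.ndarray                      # (n_items - 1, 4)
    items: list[list[str]]             # member ids per original item

    @property
    def n_items(self) -> int:
        return len(self.items)


def _enforce_monotone(Z: np.ndarray) -> np.ndarray:
    """Raise each merge height to at least the heights of its child merges."""
    Z = Z.copy()
    n = Z.shape[0] + 1
    heights = np.zeros(2 * n - 1)
    for i in range(Z.shape[0]):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        h = max(Z[i, 2], heights[a], heights[b])
        Z[i, 2] = h
        heights[n + i] = h
    return Z


def _leaf_path_distances(tree: BisectingTree) -> tuple[np.ndarray, list[BisectNode]]:
    """Pairwise branch-length path distances between bisecting-tree leaves."""
    leaves = tree.leaves()
    order = {id(l): i for i, l in enumerate(leaves)}
    k = len(leaves)
    D = np.zeros((k, k))

    def walk(node: BisectNode) -> dict[int, float]:
        """leaf index -> distance from this node, accumulating cross pairs."""
        if node.is_leaf:
            return {order[id(node)]: 0.0}
        bl_left = node.sse - node.left.sse
        bl_right = node.sse - node.right.sse
        dl = {i: d + bl_left for i, d in walk(node.left).items()}
        dr = {i: d + bl_right for i, d in walk(node.right).items()}
        for i, di in dl.items():
            for j, dj in dr.items():
                D[i, j] = D[j, i] = di + dj
        dl.update(dr)
        return dl

    walk(tree.root)
    return D, leaves


def tree_to_linkage(tree: BisectingTree) -> MergeLinkage:
    """Convert the bisecting split tree into a single-linkage merge structure.

    The K_max leaf clusters become items; item distance is the sum of branch
    lengths (SSE differences) on the tree path between leaves.  Heights are
    made monotone with a running max so maxclust flattening is well defined.
    """
    D, leaves = _leaf_path_distances(tree)
    items = [sorted(tree.ids[i] for i in leaf.indices) for leaf in leaves]
    if len(items) == 1:
        return MergeLinkage(Z=np.zeros((0, 4)), items=items)
    Z = linkage(squareform(D, checks=False), method="single")
    return MergeLinkage(Z=_enforce_monotone(Z), items=items)


def flatten(merge: MergeLinkage, k: int) -> Partition:
    """Cut the merge structure into at most ``k`` clusters (maxclust) and lift to sequences.

    ``flatten(K_max)`` reproduces the original items exactly; for
    ``k1 < k2`` the k2 partition always refines the k1 partition because
    all cuts are height thresholds of one monotone merge tree.
    """
    if not (1 <= k <= merge.n_items):
        raise DimensionError(f"k={k} must be within [1, {merge.n_items}]")
    if merge.n_items == 1 or k == merge.n_items:
        flat = np.arange(1, merge.n_items + 1)
    else:
        flat = fcluster(merge.Z, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for item_idx, cl in enumerate(flat):
        groups.setdefault(int(cl), []).extend(merge.items[item_idx])
    assignment: dict[str, str] = {}
    for members in groups.values():
        label = min(members)
        for sid in members:
            assignment[sid] = label
    return Partition(level=f"K:{k}", assignment=assignment)


def linkage_to_tree(merge: MergeLinkage, names: Sequence[str] | None = None) -> TreeNode:
    """Rooted binary tree with branch lengths = merge-height differences.

    Leaf names default to the canonical (smallest) member id of each item.
    """
    if names is None:
        names = [min(m) for m in merge.items]
    n = merge.n_items
    if n == 1:
        return TreeNode(name=names[0], length=0.0)
    heights = np.zeros(2 * n - 1)
    nodes: list[TreeNode] = [TreeNode(name=names[i]) for i in range(n)]
    for i in range(merge.Z.shape[0]):
        a, b = int(merge.Z[i, 0]), int(merge.Z[i, 1])
        h = float(merge.Z[i, 2])
        heights[n + i] = h
        for child_idx in (a, b):
            nodes[child_idx].length = h - heights[child_idx]
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes.append(parent)
    root = nodes[-1]
    root.length = None
    return root


def agglomerative(
    vectors: EmbeddingMatrix,
    linkage_method: str = "weighted",
    metric: str = "cosine",
    max_items: int = AGGLOM_MAX_ITEMS,
) -> tuple[MergeLinkage, TreeNode]:
    """WPGMA agglomeration over cosine distances (1 - cosine similarity).

    Requires the full pairwise distance matrix; datasets beyond
    ``max_items`` raise :class:`MemoryBudgetError` advising redundancy
    reduction (e.g. clustering representatives at 70% identity) before
    agglomeration.
    """
    if vectors.n > max_items:
        raise MemoryBudgetError(
            f"{vectors.n} items exceed the {max_items}-item pairwise budget; "
            "reduce redundancy (e.g. 70% ID representatives) first")
    if vectors.n < 2:
        raise DimensionError("agglomerative clustering needs >= 2 items")
    Z = linkage(vectors.X, method=linkage_method, metric=metric)
    Z = _enforce_monotone(Z)
    merge = MergeLinkage(Z=Z, items=[[sid] for sid in vectors.ids])
    return merge, linkage_to_tree(merge, names=list(vectors.ids))


# ---------------------------------------------------------------------------
# tree summarization (collapsed clade views)


def _node_height(node: TreeNode, cache: dict[int, float]) -> float:
    """Longest path from ``node`` down to any descendant leaf."""
    key = id(node)
    if key in cache:
        return cache[key]
    if node.is_tip():
        h = 0.0
    else:
        h = max((c.length or 0.0) + _node_height(c, cache) for c in node.children)
    cache[key] = h
    return h


def summarize_tree(tree: TreeNode, k: int) -> tuple[TreeNode, dict[str, str], dict[str, TreeNode]]:
    """Collapse a tree to ``k`` clades, dendrogram style.

    Starting from the root clade, the clade with the tallest subtree is
    repeatedly split into its children until ``k`` clades exist.  Each clade
    becomes a single leaf named after its smallest member, with branch
    length = its incoming branch + the longest root-to-leaf path inside the
    clade (so collapsed branch lengths report the farthest sequence).

    Returns (collapsed tree, leaf name -> clade label, clade label ->
    original subtree copy) so any clade can be re-expanded at higher
    resolution.
    """
    n_leaves = tree.count(tips=True)
    if not (1 <= k <= n_leaves):
        raise DimensionError(f"k={k} must be within [1, {n_leaves}]")
    cache: dict[int, float] = {}
    min_leaf: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_tip():
            min_leaf[id(node)] = node.name
        else:
            min_leaf[id(node)] = min(min_leaf[id(c)] for c in node.children)
    clades: list[TreeNode] = [tree]
    while len(clades) < k:
        internal = [c for c in clades if not c.is_tip()]
        if not internal:
            break
        target = max(internal, key=lambda c: (_node_height(c, cache), ))
        # deterministic tie-break by smallest contained leaf name
        best_h = _node_height(target, cache)
        ties = [c for c in internal if _node_height(c, cache) == best_h]
        target = min(ties, key=lambda c: min_leaf[id(c)])
        clades.remove(target)
        clades.extend(target.children)
    clade_set = {id(c) for c in clades}
    labels = {id(c): min_leaf[id(c)] for c in clades}

    leaf_to_clade: dict[str, str] = {}
    subtrees: dict[str, TreeNode] = {}
    for c in clades:
        label = labels[id(c)]
        subtrees[label] = c.copy()
        for tip in ([c] if c.is_tip() else c.tips()):
            leaf_to_clade[tip.name] = label

    def rebuild(node: TreeNode) -> TreeNode:
        if id(node) in clade_set:
            return TreeNode(
                name=labels[id(node)],
                length=(node.length or 0.0) + _node_height(node, cache),
            )
        return TreeNode(length=node.length, children=[rebuild(c) for c in node.children])

    collapsed = rebuild(tree)
    return collapsed, leaf_to_clade, subtrees


def project_labels(partition: Partition, membership: Mapping[str, Sequence[str]]) -> Partition:
    """Apply representative labels back to all group members.

    ``membership`` maps each representative id to its members (e.g. the
    sequences it stands for at 100% identity).  Every member inherits its
    representative's cluster.  A representative in the partition without a
    membership entry represents only itself; a membership entry whose
    representative is absent from the partition raises
    :class:`CoverageError`.
    """
    assignment: dict[str, str] = {}
    for rep, members in membership.items():
        if rep not in partition.assignment:
            raise CoverageError(f"representative {rep!r} not in partition")
        for m in members:
            assignment[m] = partition.assignment[rep]
    for rep, cid in partition.assignment.items():
        assignment.setdefault(rep, cid)
    return Partition(level=partition.level, assignment=assignment)
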