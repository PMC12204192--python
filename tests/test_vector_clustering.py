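"""Bisecting K-means, linkage conversion, flattening, WPGMA and tree summarization."""

import numpy as np
import pytest

from seqspace import (
    agglomerative,
    bisecting_kmeans,
    flatten,
    linkage_to_tree,
    project_labels,
    read_newick,
    summarize_tree,
    synth_embeddings,
    tree_to_linkage,
    write_newick,
)
from seqspace.agreement import ari
from seqspace.components import Partition
from seqspace.embedding import EmbeddingMatrix
from seqspace.errors import CoverageError, DimensionError, MemoryBudgetError
from seqspace.vector_clustering import BisectNode, BisectingTree, MergeLinkage


def emb_from(X, prefix="s"):
    return EmbeddingMatrix([f"{prefix}{i:03d}" for i in range(len(X))], np.asarray(X, float))


def random_bisect_tree(rng: np.random.Generator, n_leaves: int) -> BisectingTree:
    """A structurally random bisecting tree with valid (monotone) SSE values."""
    def split(indices):
        if len(indices) == 1 or (len(indices) > 1 and rng.random() < 0.0):
            pass
        if len(indices) == 1:
            return BisectNode(indices=indices, sse=0.0), 1
        cut = int(rng.integers(1, len(indices)))
        left, nl = split(indices[:cut])
        right, nr = split(indices[cut:])
        node = BisectNode(indices=indices,
                          sse=left.sse + right.sse + float(rng.exponential(1.0)) + 1e-6,
                          left=left, right=right)
        return node, nl + nr

    root, _ = split(rng.permutation(n_leaves))
    return BisectingTree(root=root, ids=[f"x{i:04d}" for i in range(n_leaves)])


class TestBisectingKMeans:
    def test_two_point_masses_closed_form_sse(self):
        # n points at -5 and n at +5: SSE(root) = 2n * 5^2, children SSE = 0
        n = 6
        X = np.r_[np.full((n, 1), -5.0), np.full((n, 1), 5.0)]
        tree = bisecting_kmeans(emb_from(X), k_max=2, seed=0)
        leaves = tree.leaves()
        assert len(leaves) == 2
        assert tree.root.sse == pytest.approx(2 * n * 25.0)
        assert all(l.sse == pytest.approx(0.0) for l in leaves)
        sets = {frozenset(l.indices.tolist()) for l in leaves}
        assert sets == {frozenset(range(n)), frozenset(range(n, 2 * n))}

    def test_k_max_equals_n_all_singletons(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 3))
        tree = bisecting_kmeans(emb_from(X), k_max=9, seed=1)
        leaves = tree.leaves()
        assert len(leaves) == 9
        assert all(l.sse == pytest.approx(0.0) for l in leaves)

    def test_recovers_planted_families(self):
        emb, _, fam = synth_embeddings(n_super=2, fam_per_super=4, members_per_fam=12,
                                       sep_fam=10.0, noise_sd=1.0, seed=2)
        tree = bisecting_kmeans(emb, k_max=8, seed=2)
        assert ari(tree.leaf_partition(), fam) == pytest.approx(1.0)

    def test_k_max_out_of_range(self):
        emb = emb_from(np.zeros((4, 2)))
        with pytest.raises(DimensionError):
            bisecting_kmeans(emb, k_max=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        t1 = bisecting_kmeans(emb_from(X), k_max=10, seed=7)
        t2 = bisecting_kmeans(emb_from(X), k_max=10, seed=7)
        assert t1.leaf_partition().assignment == t2.leaf_partition().assignment


def brute_single_linkage(D):
    """Naive single-linkage agglomeration; returns sorted merge heights."""
    D = D.copy().astype(float)
    active = {i: {i} for i in range(len(D))}
    heights = []
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a < b:
                    d = min(D[i, j] for i in active[a] for j in active[b])
                    if best is None or d < best[0]:
                        best = (d, a, b)
        d, a, b = best
        heights.append(d)
        active[a] |= active[b]
        del active[b]
    return heights


class TestTreeToLinkage:
    def test_two_leaf_tree_single_merge_at_branch_sum(self):
        left = BisectNode(indices=np.array([0]), sse=0.0)
        right = BisectNode(indices=np.array([1]), sse=0.0)
        root = BisectNode(indices=np.array([0, 1]), sse=8.0, left=left, right=right)
        tree = BisectingTree(root=root, ids=["a", "b"])
        merge = tree_to_linkage(tree)
        assert merge.Z.shape == (1, 4)
        assert merge.Z[0, 2] == pytest.approx(16.0)  # both branches are 8

    def test_caterpillar_matches_brute_force_single_linkage(self):
        # caterpillar: (((0,1),2),3) with chosen SSEs
        l0 = BisectNode(indices=np.array([0]), sse=0.0)
        l1 = BisectNode(indices=np.array([1]), sse=0.0)
        n01 = BisectNode(indices=np.array([0, 1]), sse=2.0, left=l0, right=l1)
        l2 = BisectNode(indices=np.array([2]), sse=0.0)
        n012 = BisectNode(indices=np.array([0, 1, 2]), sse=5.0, left=n01, right=l2)
        l3 = BisectNode(indices=np.array([3]), sse=0.0)
        root = BisectNode(indices=np.arange(4), sse=11.0, left=n012, right=l3)
        tree = BisectingTree(root=root, ids=list("abcd"))
        # hand path distances: d01=4, d02=3+5=8, d12=3+5=8... computed from SSE diffs
        D = np.zeros((4, 4))
        bl = {"01": 2.0, "012_01": 3.0, "012_2": 5.0, "r_012": 6.0, "r_3": 11.0}
        D[0, 1] = D[1, 0] = 2 * bl["01"]
        D[0, 2] = D[2, 0] = bl["01"] + bl["012_01"] + bl["012_2"]
        D[1, 2] = D[2, 1] = bl["01"] + bl["012_01"] + bl["012_2"]
        D[0, 3] = D[3, 0] = bl["01"] + bl["012_01"] + bl["r_012"] + bl["r_3"]
        D[1, 3] = D[3, 1] = bl["01"] + bl["012_01"] + bl["r_012"] + bl["r_3"]
        D[2, 3] = D[3, 2] = bl["012_2"] + bl["r_012"] + bl["r_3"]
        merge = tree_to_linkage(tree)
        assert np.allclose(sorted(merge.Z[:, 2]), brute_single_linkage(D))

    def test_heights_non_decreasing_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree = random_bisect_tree(rng, int(rng.integers(3, 25)))
            merge = tree_to_linkage(tree)
            heights = merge.Z[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)


class TestFlatten:
    def test_k_one_single_cluster(self):
        rng = np.random.default_rng(6)
        merge = tree_to_linkage(random_bisect_tree(rng, 10))
        assert flatten(merge, 1).n_clusters == 1

    def test_k_n_items_reproduces_items(self):
        rng = np.random.default_rng(7)
        tree = random_bisect_tree(rng, 12)
        merge = tree_to_linkage(tree)
        part = flatten(merge, 12)
        assert part.n_clusters == 12

    def test_flatten_kmax_equals_bisecting_leaves(self):
        emb, _, _ = synth_embeddings(n_super=2, fam_per_super=2, members_per_fam=10, seed=8)
        tree = bisecting_kmeans(emb, k_max=10, seed=8)
        merge = tree_to_linkage(tree)
        assert flatten(merge, 10).assignment == tree.leaf_partition().assignment

    def test_cross_k_refinement_on_random_trees(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(4, 30))
            merge = tree_to_linkage(random_bisect_tree(rng, n))
            ks = sorted(set(rng.integers(1, n + 1, size=6)))
            parts = [flatten(merge, k) for k in ks]
            for coarse, fine in zip(parts, parts[1:]):
                # every fine cluster lies inside one coarse cluster
                for members in fine.clusters().values():
                    assert len({coarse.assignment[m] for m in members}) == 1


def brute_wpgma_heights(D):
    """Independent WPGMA recurrence: d(new, x) = (d(a,x) + d(b,x)) / 2."""
    D = D.copy().astype(float)
    n = len(D)
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    heights = []
    while len(active) > 1:
        sub = D[np.ix_(active, active)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        a, b = active[i], active[j]
        heights.append(D[a, b])
        new = [(D[a, x] + D[b, x]) / 2 for x in active if x not in (a, b)]
        rest = [x for x in active if x not in (a, b)]
        for x, d in zip(rest, new):
            D[a, x] = D[x, a] = d
        active = rest + [a]
    return sorted(heights)


class TestAgglomerative:
    def test_identical_pair_merges_first_at_zero(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        merge, _ = agglomerative(emb_from(X))
        assert merge.Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(merge.Z[0, 0]), int(merge.Z[0, 1])} == {0, 1}

    def test_orthogonal_vectors_first_merge_at_one(self):
        merge, _ = agglomerative(emb_from(np.eye(4)))
        assert merge.Z[0, 2] == pytest.approx(1.0)

    def test_wpgma_heights_match_brute_force_recurrence(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 5))
        merge, _ = agglomerative(emb_from(X))
        sim = X @ X.T / (np.linalg.norm(X, axis=1)[:, None] * np.linalg.norm(X, axis=1)[None, :])
        D = 1 - sim
        np.fill_diagonal(D, 0)
        assert np.allclose(sorted(merge.Z[:, 2]), brute_wpgma_heights(D), atol=1e-10)

    def test_memory_budget_enforced(self):
        rng = np.random.default_rng(11)
        emb = emb_from(rng.normal(size=(12, 3)))
        with pytest.raises(MemoryBudgetError):
            agglomerative(emb, max_items=10)

    def test_recovers_planted_structure(self):
        emb, sup, fam = synth_embeddings(n_super=3, fam_per_super=3, members_per_fam=8,
                                         sep_fam=10.0, noise_sd=1.0, seed=12)
        merge, _ = agglomerative(emb)
        assert ari(flatten(merge, 9), fam) == pytest.approx(1.0)
        assert ari(flatten(merge, 3), sup) == pytest.approx(1.0)


def root_to_tip_depths(tree):
    out = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        out[tip.name] = d
    return out


class TestSummarizeTree:
    def random_merge_tree(self, rng, n):
        X = rng.normal(size=(n, 4))
        merge, tree = agglomerative(emb_from(X))
        return tree

    def test_k_equals_leaf_count_tree_unchanged(self):
        rng = np.random.default_rng(13)
        tree = self.random_merge_tree(rng, 8)
        collapsed, mapping, _ = summarize_tree(tree, 8)
        assert root_to_tip_depths(collapsed) == pytest.approx(root_to_tip_depths(tree))
        assert all(leaf == clade for leaf, clade in mapping.items())

    def test_k_one_single_leaf_of_tree_height(self):
        rng = np.random.default_rng(14)
        tree = self.random_merge_tree(rng, 10)
        collapsed, mapping, _ = summarize_tree(tree, 1)
        height = max(root_to_tip_depths(tree).values())
        (tip,) = collapsed.tips() if not collapsed.is_tip() else (collapsed,)
        assert tip.length == pytest.approx(height)
        assert len(set(mapping.values())) == 1

    def test_collapsed_lengths_equal_farthest_member(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            tree = self.random_merge_tree(rng, n)
            k = int(rng.integers(2, n))
            original_depths = root_to_tip_depths(tree)
            collapsed, mapping, _ = summarize_tree(tree, k)
            collapsed_depths = root_to_tip_depths(collapsed)
            for clade in set(mapping.values()):
                members = [leaf for leaf, c in mapping.items() if c == clade]
                assert collapsed_depths[clade] == pytest.approx(
                    max(original_depths[m] for m in members), abs=1e-9)

    def test_subtrees_retrievable(self):
        rng = np.random.default_rng(16)
        tree = self.random_merge_tree(rng, 12)
        _, mapping, subtrees = summarize_tree(tree, 3)
        for clade, sub in subtrees.items():
            tips = {t.name for t in sub.tips()} or {sub.name}
            assert tips == {leaf for leaf, c in mapping.items() if c == clade}

    def test_round_trips_through_newick(self):
        rng = np.random.default_rng(17)
        tree = self.random_merge_tree(rng, 9)
        collapsed, _, _ = summarize_tree(tree, 4)
        back = read_newick(write_newick(collapsed))
        assert root_to_tip_depths(back) == pytest.approx(root_to_tip_depths(collapsed))


class TestProjectLabels:
    def test_identity_membership_unchanged(self):
        p = Partition("K:2", {"a": "a", "b": "b"})
        out = project_labels(p, {"a": ["a"], "b": ["b"]})
        assert out.assignment == p.assignment

    def test_members_inherit_representative_cluster(self):
        p = Partition("K:2", {"r1": "c1", "r2": "c2"})
        out = project_labels(p, {"r1": ["m1", "m2", "m3"], "r2": ["m4", "m5", "m6"]})
        assert len(out.assignment) == 8
        assert out.assignment["m2"] == "c1" and out.assignment["m5"] == "c2"
        assert out.n_clusters == p.n_clusters

    def test_unknown_representative_rejected(self):
        p = Partition("K:1", {"r1": "c1"})
        with pytest.raises(CoverageError):
            project_labels(p, {"ghost": ["m1"]})
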