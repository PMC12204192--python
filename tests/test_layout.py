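"""Circle packing, nesting, filtering and full layout construction."""

import numpy as np
import pytest

from seqspace import (
    ClusterHierarchy,
    Layout,
    Partition,
    build_layout,
    filter_clusters,
    nest,
    pack_siblings,
)
from seqspace.io import AnnotationTable
from seqspace.layout import Circle, TOL_FRACTION, annotate_layout, read_layout, write_layout


def overlap_depths(circles):
    out = []
    for i in range(len(circles)):
        for j in range(i + 1, len(circles)):
            xi, yi, ri = circles[i]
            xj, yj, rj = circles[j]
            out.append(ri + rj - np.hypot(xi - xj, yi - yj))
    return out


class TestPackSiblings:
    def test_single_sibling_centered_at_origin(self):
        assert pack_siblings([9]) == [(0.0, 0.0, 3.0)]

    def test_two_equal_siblings_tangent_and_symmetric(self):
        (x1, y1, r1), (x2, y2, r2) = pack_siblings([16, 16], seed=3)
        gap = np.hypot(x1 - x2, y1 - y2) - (r1 + r2)
        assert abs(gap) < TOL_FRACTION * r1  # tangent within tolerance
        assert np.allclose([x1 + x2, y1 + y2], 0.0, atol=1e-9)

    def test_no_deep_overlaps_and_exact_area_proportionality(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(1, 1000, size=100).tolist()
        packed = pack_siblings(sizes, seed=1)
        radii = np.array([r for _, _, r in packed])
        tol = TOL_FRACTION * radii.min()
        assert max(overlap_depths(packed)) <= tol + 1e-9
        areas = np.pi * radii**2
        assert np.allclose(areas / areas[0], np.array(sizes) / sizes[0], rtol=1e-9)

    def test_deterministic_under_seed(self):
        sizes = [5, 10, 3, 42, 7]
        assert pack_siblings(sizes, seed=9) == pack_siblings(sizes, seed=9)

    def test_permutation_changes_only_labels(self):
        sizes = [4, 9, 25, 16]
        p1 = pack_siblings(sizes, seed=2)
        p2 = pack_siblings(sizes[::-1], seed=2)
        assert sorted(r for _, _, r in p1) == sorted(r for _, _, r in p2)


class TestNest:
    def parent(self, r=10.0):
        return Circle("P", "L0", 5.0, -3.0, r, int(r * r))

    def test_single_small_child_concentric(self):
        placed, s = nest(self.parent(), [(0.0, 0.0, 2.0)])
        assert placed == [(5.0, -3.0, 2.0)] and s == 1.0

    def test_oversized_children_rescaled_to_margin(self):
        parent = self.parent(r=5.0)
        packed = [(-10.0, 0.0, 4.0), (10.0, 0.0, 4.0)]
        placed, s = nest(parent, packed)
        extent = max(np.hypot(x - parent.x, y - parent.y) + r for x, y, r in placed)
        assert extent == pytest.approx(0.95 * parent.radius)
        assert s < 1.0

    def test_similarity_transform_preserves_relative_overlaps(self):
        parent = self.parent(r=6.0)
        packed = [(-3.0, 0.0, 2.0), (3.0, 0.0, 2.0), (0.0, 3.0, 1.0)]
        before = np.array(overlap_depths(packed))
        placed, s = nest(parent, packed)
        after = np.array(overlap_depths(placed))
        assert np.allclose(after, before * s, atol=1e-9)


def three_level_hierarchy(n_top=3, fan=3, leaf_size=4):
    """Synthetic nested partitions: n_top -> n_top*fan -> n_top*fan*fan clusters."""
    ids, l0, l1, l2 = [], {}, {}, {}
    for a in range(n_top):
        for b in range(fan):
            for c in range(fan):
                for m in range(leaf_size):
                    sid = f"i{a}_{b}_{c}_{m}"
                    ids.append(sid)
                    l0[sid] = f"A{a}"
                    l1[sid] = f"A{a}B{b}"
                    l2[sid] = f"A{a}B{b}C{c}"
    return ClusterHierarchy(partitions=[
        Partition("L0", l0), Partition("L1", l1), Partition("L2", l2)])


class TestFilterClusters:
    def test_min_size_drops_small_clusters(self):
        hier = three_level_hierarchy(leaf_size=4)
        hier.partitions[2].assignment["extra"] = "tiny"
        hier.partitions[1].assignment["extra"] = "tinyB"
        hier.partitions[0].assignment["extra"] = "tinyA"
        hier.parent_maps = [  # rebuild after mutation
            __import__("seqspace").build_parent_map(hier.partitions[0], hier.partitions[1]),
            __import__("seqspace").build_parent_map(hier.partitions[1], hier.partitions[2]),
        ]
        kept = filter_clusters(hier, min_size=5)
        assert "tiny" not in kept["L2"]
        assert all(len(hier.partitions[1].clusters()[c]) >= 5 for c in kept["L1"] if c != "tinyB")

    def test_must_contain_keeps_chain(self):
        hier = three_level_hierarchy()
        kept = filter_clusters(hier, must_contain={"i1_2_0_0"})
        assert kept["L0"] == {"A1"}
        assert kept["L1"] == {"A1B2"}
        assert kept["L2"] == {"A1B2C0"}

    def test_no_criteria_identity(self):
        hier = three_level_hierarchy()
        kept = filter_clusters(hier)
        assert kept["L2"] == set(hier.partitions[2].clusters())

    def test_ancestors_of_kept_clusters_survive(self):
        hier = three_level_hierarchy(leaf_size=2)
        kept = filter_clusters(hier, must_contain={"i0_0_0_0"})
        assert "A0" in kept["L0"] and "A0B0" in kept["L1"]


class TestBuildLayout:
    def test_containment_within_parent(self):
        hier = three_level_hierarchy()
        layout = build_layout(hier, seed=4)
        by_id = {(c.level, c.cluster_id): c for c in layout.circles}
        levels = hier.levels()
        for c in layout.circles:
            if c.parent_id is None:
                continue
            parent = by_id[(levels[levels.index(c.level) - 1], c.parent_id)]
            d = np.hypot(c.x - parent.x, c.y - parent.y) + c.radius
            assert d <= 0.95 * parent.radius * (1 + 1e-6)

    def test_rerun_is_byte_identical(self, tmp_path):
        hier = three_level_hierarchy()
        for name in ("a", "b"):
            write_layout(tmp_path / name, build_layout(hier, seed=7))
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()

    def test_filtered_clusters_absent(self):
        hier = three_level_hierarchy()
        layout = build_layout(hier, must_contain={"i2_1_1_0"}, seed=0)
        ids = {(c.level, c.cluster_id) for c in layout.circles}
        assert ids == {("L0", "A2"), ("L1", "A2B1"), ("L2", "A2B1C1")}

    def test_layout_file_round_trip(self, tmp_path):
        hier = three_level_hierarchy(n_top=2, fan=2)
        layout = build_layout(hier, seed=1)
        write_layout(tmp_path / "l.tsv", layout)
        back = read_layout(tmp_path / "l.tsv")
        orig = sorted((c.level, c.cluster_id, c.x, c.y, c.radius, c.size, c.parent_id)
                      for c in layout.circles)
        round_ = sorted((c.level, c.cluster_id, c.x, c.y, c.radius, c.size, c.parent_id)
                        for c in back.circles)
        assert orig == round_


class TestAnnotateLayout:
    def make(self):
        hier = three_level_hierarchy(n_top=1, fan=1, leaf_size=3)
        layout = build_layout(hier, seed=0)
        return hier, layout

    def test_uniform_function_fill(self):
        hier, layout = self.make()
        ann = AnnotationTable({sid: {"function": "oxidase"} for sid in hier.partitions[0].universe()})
        rows = annotate_layout(layout, hier, ann)
        assert all(r["fill"] == "oxidase" and not r["mixed"] for r in rows)

    def test_mixed_functions_flagged(self):
        hier, layout = self.make()
        ids = sorted(hier.partitions[0].universe())
        ann = AnnotationTable({ids[0]: {"function": "a"}, ids[1]: {"function": "b"}})
        rows = annotate_layout(layout, hier, ann)
        assert all(r["mixed"] for r in rows)
        assert all(r["functions"] == "a;b" for r in rows)

    def test_unannotated_cluster_null_style(self):
        hier, layout = self.make()
        rows = annotate_layout(layout, hier, AnnotationTable())
        assert all(r["fill"] is None and r["fill_color"] is None for r in rows)
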