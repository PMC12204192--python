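"""Hierarchical cluster plot layout: filtered, physics-packed nested circles.

Every cluster is a circle whose area is proportional to its member count;
circles of sibling clusters are packed together with a deterministic
overlap-relaxation integrator (seeded sunflower-spiral initialization,
pairwise push-apart of overlapping circles plus a centripetal contraction
toward the group centroid), and each packed sibling group is then nested
inside its parent circle.  The result is persisted as a renderer-independent
tab-separated layout file; rendering itself (matplotlib, bokeh, anything)
is outside the core contract.

This replaces force-directed SSN node-edge layout, which is infeasible for
networks with millions of edges: packing scales with the number of clusters,
not the number of edges.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .components import ClusterHierarchy
from .io import AnnotationTable, category_color

#: fraction of the parent radius children must fit within
CONTAINMENT_FACTOR = 0.95
#: overlap tolerance, as a fraction of the smallest sibling radius
TOL_FRACTION = 1e-3


@dataclass
class Circle:
    """One cluster circle: level, center, radius, parent link and group scale."""

    cluster_id: str
    level: str
    x: float
    y: float
    radius: float
    size: int
    parent_id: str | None = None
    scale_factor: float = 1.0


@dataclass
class Layout:
    circles: list[Circle]
    seed: int = 0
    filters: dict = field(default_factory=dict)

    def at_level(self, level: str) -> list[Circle]:
        return [c for c in self.circles if c.level == level]


def filter_clusters(
    hierarchy: ClusterHierarchy,
    min_size: int | None = None,
    must_contain: Iterable[str] | None = None,
) -> dict[str, set[str]]:
    """Select clusters above a size or containing given sequences, plus ancestors.

    With no criteria every cluster is kept.  When both criteria are given a
    cluster passes if it meets either.  All ancestors of kept clusters are
    kept too, so nesting stays well-formed.
    """
    contain = set(must_contain) if must_contain is not None else None
    kept: dict[str, set[str]] = {}
    for part in hierarchy.partitions:
        if min_size is None and contain is None:
            kept[part.level] = set(part.clusters())
            continue
        level_keep: set[str] = set()
        for cid, members in part.clusters().items():
            if min_size is not None and len(members) >= min_size:
                level_keep.add(cid)
            elif contain is not None and members & contain:
                level_keep.add(cid)
        kept[part.level] = level_keep
    # propagate ancestors, fine -> coarse
    for i in range(len(hierarchy.partitions) - 1, 0, -1):
        fine = hierarchy.partitions[i]
        coarse = hierarchy.partitions[i - 1]
        pm = hierarchy.parent_maps[i - 1]
        for cid in kept[fine.level]:
            kept[coarse.level].add(pm[cid])
    return kept


def _resolve_pass(pos: np.ndarray, r: np.ndarray) -> float:
    """One push-apart pass; returns the deepest overlap before the pass."""
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2 * r.max(), output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    delta = pos[i] - pos[j]
    dist = np.hypot(delta[:, 0], delta[:, 1])
    overlap = r[i] + r[j] - dist
    mask = overlap > 0
    if not mask.any():
        return 0.0
    i, j, delta, dist, overlap = i[mask], j[mask], delta[mask], dist[mask], overlap[mask]
    # coincident centers: separate along a deterministic per-pair direction
    zero = dist < 1e-12
    if zero.any():
        ang = 2.399963229728653 * (i[zero] * 31 + j[zero]).astype(float)
        delta[zero] = np.c_[np.cos(ang), np.sin(ang)]
        dist[zero] = 1.0
    unit = delta / dist[:, None]
    shift = 0.5 * overlap[:, None] * unit
    move = np.zeros_like(pos)
    np.add.at(move, i, shift)
    np.add.at(move, j, -shift)
    pos += move
    return float(overlap.max())


def pack_siblings(
    sizes: Sequence[int],
    seed: int = 0,
    outer_iters: int = 50,
    contract: float = 0.9,
    max_resolve: int = 500,
) -> list[tuple[float, float, float]]:
    """Pack sibling circles with radii sqrt(size), returning (x, y, radius) triples.

    Area proportionality to cluster size is exact within the group.
    Iterative relaxation alternates a centripetal contraction toward the
    area-weighted centroid with overlap resolution; a final resolution loop
    runs until the deepest overlap is below ``TOL_FRACTION * min(radius)``.
    Deterministic under ``seed`` (the only randomness is the seeded rotation
    of the sunflower-spiral initialization); output is finally recentred so
    the area-weighted centroid sits at the origin.
    """
    sizes_arr = np.asarray(sizes, dtype=float)
    if len(sizes_arr) == 0 or (sizes_arr <= 0).any():
        raise ValueError("sizes must be positive")
    r = np.sqrt(sizes_arr)
    n = len(r)
    if n == 1:
        return [(0.0, 0.0, float(r[0]))]
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3 - np.sqrt(5))
    k = np.arange(n)
    ring = np.sqrt(np.sum(r**2)) * np.sqrt((k + 0.5) / n)
    theta = k * golden + offset
    pos = np.c_[ring * np.cos(theta), ring * np.sin(theta)]
    w = (r**2)[:, None]
    tol = TOL_FRACTION * r.min()
    # the per-pass report is the pre-move overlap, so converge to a quarter
    # of the tolerance: residual post-move overlaps stay below tol
    target = 0.25 * tol
    for _ in range(outer_iters):
        for _ in range(8):
            if _resolve_pass(pos, r) <= target:
                break
        centroid = (pos * w).sum(axis=0) / w.sum()
        pos = centroid + (pos - centroid) * contract
    for _ in range(max_resolve):
        if _resolve_pass(pos, r) <= target:
            break
    centroid = (pos * w).sum(axis=0) / w.sum()
    pos -= centroid
    return [(float(x), float(y), float(rr)) for (x, y), rr in zip(pos, r)]


def nest(
    parent: Circle,
    packed: Sequence[tuple[float, float, float]],
    margin: float = CONTAINMENT_FACTOR,
) -> tuple[list[tuple[float, float, float]], float]:
    """Place packed children inside a parent circle.

    Children are translated so their area-weighted centroid coincides with
    the parent center, then uniformly rescaled (about the parent center) by
    the largest factor s <= 1 such that every child lies within
    ``margin * parent.radius``.  The similarity transform preserves relative
    geometry, so child/child overlaps are unchanged.  Returns the placed
    children and s.
    """
    arr = np.asarray(packed, dtype=float)
    w = arr[:, 2] ** 2
    centroid = (arr[:, :2] * w[:, None]).sum(axis=0) / w.sum()
    local = arr[:, :2] - centroid
    extent = float(np.max(np.hypot(local[:, 0], local[:, 1]) + arr[:, 2]))
    s = 1.0 if extent <= 0 else min(1.0, margin * parent.radius / extent)
    placed = [
        (parent.x + s * lx, parent.y + s * ly, s * rr)
        for (lx, ly), rr in zip(local, arr[:, 2])
    ]
    return placed, s


def _derive_seed(seed: int, level: str, parent: str) -> int:
    return zlib.crc32(f"{seed}|{level}|{parent}".encode()) & 0x7FFFFFFF


def build_layout(
    hierarchy: ClusterHierarchy,
    min_size: int | None = None,
    must_contain: Iterable[str] | None = None,
    seed: int = 0,
) -> Layout:
    """Pack the full hierarchy into nested circles.

    Roots (the coarsest level) are packed as one sibling group in global
    coordinates; each kept cluster's children are then packed recursively
    and nested inside it.  Per-group seeds are derived deterministically
    from the master seed, the level and the parent id, so reruns are
    byte-identical.
    """
    kept = filter_clusters(hierarchy, min_size=min_size, must_contain=must_contain)
    circles: list[Circle] = []
    by_id: dict[tuple[str, str], Circle] = {}
    levels = hierarchy.levels()

    top = hierarchy.partitions[0]
    top_ids = sorted(kept[top.level])
    if top_ids:
        sizes = top.sizes()
        packed = pack_siblings([sizes[c] for c in top_ids], seed=_derive_seed(seed, top.level, "<root>"))
        for cid, (x, y, rr) in zip(top_ids, packed):
            c = Circle(cid, top.level, x, y, rr, sizes[cid])
            circles.append(c)
            by_id[(top.level, cid)] = c

    for li in range(1, len(levels)):
        part = hierarchy.partitions[li]
        pm = hierarchy.parent_maps[li - 1]
        sizes = part.sizes()
        groups: dict[str, list[str]] = {}
        for cid in kept[part.level]:
            groups.setdefault(pm[cid], []).append(cid)
        for parent_id in sorted(groups):
            parent_circle = by_id[(levels[li - 1], parent_id)]
            child_ids = sorted(groups[parent_id])
            packed = pack_siblings(
                [sizes[c] for c in child_ids],
                seed=_derive_seed(seed, part.level, parent_id),
            )
            placed, s = nest(parent_circle, packed)
            for cid, (x, y, rr) in zip(child_ids, placed):
                c = Circle(cid, part.level, x, y, rr, sizes[cid],
                           parent_id=parent_id, scale_factor=s)
                circles.append(c)
                by_id[(part.level, cid)] = c

    return Layout(circles=circles, seed=seed,
                  filters={"min_size": min_size,
                           "must_contain": sorted(must_contain) if must_contain else None})


LAYOUT_HEADER = "level\tcluster_id\tparent_id\tx\ty\tradius\tsize\tscale_factor"


def write_layout(path: str | Path, layout: Layout) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(LAYOUT_HEADER + "\n")
        for c in sorted(layout.circles, key=lambda c: (c.level, c.cluster_id)):
            fh.write(
                f"{c.level}\t{c.cluster_id}\t{c.parent_id or ''}\t"
                f"{float(c.x)!r}\t{float(c.y)!r}\t{float(c.radius)!r}\t"
                f"{c.size}\t{float(c.scale_factor)!r}\n"
            )


def read_layout(path: str | Path) -> Layout:
    circles: list[Circle] = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            level, cid, parent, x, y, rr, size, s = line.rstrip("\n").split("\t")
            circles.append(Circle(cid, level, float(x), float(y), float(rr),
                                  int(size), parent or None, float(s)))
    return Layout(circles=circles)


def annotate_layout(
    layout: Layout,
    hierarchy: ClusterHierarchy,
    annotations: AnnotationTable,
    function_key: str = "function",
    taxon_key: str = "taxon_genus",
) -> list[dict]:
    """Per-circle style summaries: majority-function fill, taxon-set outline.

    A circle whose members carry more than one function is flagged
    ``mixed`` with all functions listed; unannotated circles get null
    styles.  Category colors are deterministic.
    """
    members_by = {p.level: p.clusters() for p in hierarchy.partitions}
    rows: list[dict] = []
    for c in sorted(layout.circles, key=lambda c: (c.level, c.cluster_id)):
        members = members_by[c.level][c.cluster_id]
        funcs = sorted({f for f in (annotations.get(m, function_key) for m in members) if f})
        taxa = sorted({t for t in (annotations.get(m, taxon_key) for m in members) if t})
        if not funcs:
            fill, mixed = None, False
        else:
            counts: dict[str, int] = {}
            for m in members:
                f = annotations.get(m, function_key)
                if f:
                    counts[f] = counts.get(f, 0) + 1
            top = max(counts.values())
            fill = min(f for f, n in counts.items() if n == top)
            mixed = len(funcs) > 1
        rows.append({
            "level": c.level,
            "cluster_id": c.cluster_id,
            "fill": fill,
            "fill_color": category_color(fill) if fill else None,
            "mixed": mixed,
            "functions": ";".join(funcs),
            "outline": ";".join(taxa),
        })
    return rows
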