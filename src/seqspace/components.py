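"""Streaming connected-components clustering of the SSN and the cross-cutoff hierarchy.

A sequence neighborhood at a bitscore cut-off is a connected component of
the SSN restricted to edges with bitscore >= the cut-off ("above a cut-off"
is inclusive so printed integer cut-offs keep their ties).  Components are
computed by streaming the edge file in chunks: each chunk builds a local
disjoint-set forest, and chunk results are merged by unioning clusters that
share any member.  The merge is associative and commutative, so the result
is independent of chunk size and processing order; peak memory is
O(nodes + chunk_edges), never O(edges).

Because the edge set at a higher cut-off is a subset of the edge set at a
lower one, partitions across an increasing cut-off ladder are nested:
clusters at lower cut-offs act as parent neighborhoods for the clusters
that separate at higher cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import RefinementError, UniverseError
from .network import CutoffSet, EdgeStore


class DisjointSetForest:
    """Union-find with union-by-size and path compression."""

    __slots__ = ("parent", "size")

    def __init__(self, ids: Iterable[str] = ()):  # lazily extended by union/add
        self.parent: dict[str, str] = {i: i for i in ids}
        self.size: dict[str, int] = {i: 1 for i in self.parent}

    def add(self, x: str) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.size[x] = 1

    def find(self, x: str) -> str:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        self.add(a)
        self.add(b)
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return out


@dataclass
class Partition:
    """One clustering of the id universe at a labelled level."""

    level: str
    assignment: dict[str, str]

    def universe(self) -> set[str]:
        return set(self.assignment)

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sid, cid in self.assignment.items():
            out.setdefault(cid, set()).add(sid)
        return out

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cid in self.assignment.values():
            out[cid] = out.get(cid, 0) + 1
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def labels(self, order: Sequence[str]) -> list[str]:
        """Cluster labels in a given id order (for ARI/AMI style comparisons)."""
        return [self.assignment[i] for i in order]


def canonical_labels(partition: Partition) -> Partition:
    """Relabel every cluster to its lexicographically smallest member id.

    Canonical labels are deterministic across runs, chunkings and edge-file
    orderings; the operation is idempotent.
    """
    smallest: dict[str, str] = {}
    for sid, cid in partition.assignment.items():
        if cid not in smallest or sid < smallest[cid]:
            smallest[cid] = sid
    return Partition(
        level=partition.level,
        assignment={sid: smallest[cid] for sid, cid in partition.assignment.items()},
    )


def _forest_to_partition(forest: DisjointSetForest, universe: frozenset[str], level: str) -> Partition:
    assignment: dict[str, str] = {}
    # canonical label = smallest member id of each component
    smallest: dict[str, str] = {}
    for x in forest.parent:
        r = forest.find(x)
        if r not in smallest or x < smallest[r]:
            smallest[r] = x
    for x in universe:
        if x in forest.parent:
            assignment[x] = smallest[forest.find(x)]
        else:
            assignment[x] = x  # singleton: no surviving edge
    return Partition(level=level, assignment=assignment)


def level_label(cutoff: float) -> str:
    return f"bitscore:{cutoff:g}"


def components_at_cutoff(store: EdgeStore, cutoff: float, chunk_edges: int = 1_000_000) -> Partition:
    """Connected components of the SSN thresholded at ``cutoff``.

    Edges with bitscore < cutoff are ignored.  Each chunk is clustered with
    a local forest; local clusters are then merged into a global forest by
    unioning members, reproducing the chunk-merge semantics while keeping
    memory bounded by the node universe plus one chunk.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    global_forest = DisjointSetForest()
    for batch in store.iter_edges(chunk_edges=chunk_edges):
        local = DisjointSetForest()
        for a, b, s in batch:
            if s >= cutoff:
                local.union(a, b)
        # merge: union together every member of each local cluster
        for members in local.groups().values():
            first = members[0]
            for other in members[1:]:
                global_forest.union(first, other)
    return _forest_to_partition(global_forest, store.node_ids, level_label(cutoff))


@dataclass
class ClusterHierarchy:
    """Nested partitions over an ordered cut-off ladder (coarse -> fine).

    ``parent_maps[i]`` maps each cluster of ``partitions[i+1]`` to the
    cluster of ``partitions[i]`` that contains it.
    """

    partitions: list[Partition]
    parent_maps: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.parent_maps and len(self.partitions) > 1:
            self.parent_maps = [
                build_parent_map(c, f) for c, f in zip(self.partitions, self.partitions[1:])
            ]

    def levels(self) -> list[str]:
        return [p.level for p in self.partitions]

    def by_level(self, level: str) -> Partition:
        for p in self.partitions:
            if p.level == level:
                return p
        raise KeyError(level)

    def children(self, level_index: int, cluster_id: str) -> list[str]:
        """Clusters at level ``level_index + 1`` whose parent is ``cluster_id``."""
        pm = self.parent_maps[level_index]
        return sorted(c for c, p in pm.items() if p == cluster_id)


def build_parent_map(coarse: Partition, fine: Partition) -> dict[str, str]:
    """Map each fine cluster to the coarse cluster containing all its members.

    Raises :class:`UniverseError` on id-universe mismatch and
    :class:`RefinementError` (naming the offender) if a fine cluster spans
    more than one coarse cluster.
    """
    if coarse.universe() != fine.universe():
        raise UniverseError(
            f"universes differ between {coarse.level!r} and {fine.level!r}")
    parent: dict[str, str] = {}
    for sid, fine_cid in fine.assignment.items():
        coarse_cid = coarse.assignment[sid]
        prev = parent.get(fine_cid)
        if prev is None:
            parent[fine_cid] = coarse_cid
        elif prev != coarse_cid:
            raise RefinementError(
                f"fine cluster {fine_cid!r} spans coarse clusters {prev!r} and {coarse_cid!r}")
    return parent


def components_multi(
    store: EdgeStore,
    cutoffs: CutoffSet | Sequence[float],
    chunk_edges: int = 1_000_000,
) -> ClusterHierarchy:
    """Connected components at every cut-off of an increasing ladder, in one pass.

    One forest is maintained per cut-off; each streamed edge is applied to
    every cut-off at or below its bitscore.  Refinement of finer levels by
    coarser ones is guaranteed because higher cut-offs see a subset of the
    edges.
    """
    thresholds = list(cutoffs)
    if any(a >= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    forests = {c: DisjointSetForest() for c in thresholds}
    for batch in store.iter_edges(chunk_edges=chunk_edges):
        locals_ = {c: DisjointSetForest() for c in thresholds}
        for a, b, s in batch:
            for c in thresholds:
                if s >= c:
                    locals_[c].union(a, b)
                else:
                    break  # thresholds increasing: higher cutoffs also fail
        for c in thresholds:
            gf = forests[c]
            for members in locals_[c].groups().values():
                first = members[0]
                for other in members[1:]:
                    gf.union(first, other)
    partitions = [
        _forest_to_partition(forests[c], store.node_ids, level_label(c)) for c in thresholds
    ]
    return ClusterHierarchy(partitions=partitions)
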