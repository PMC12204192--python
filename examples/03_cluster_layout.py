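"""Hierarchical cluster plot: pack a multi-cutoff hierarchy into nested circles.

Clusters become circles with area proportional to membership; sibling
circles are packed by deterministic overlap relaxation and nested inside
their parent cluster's circle.  The layout is persisted as a plain TSV that
any renderer can draw; no edges are ever drawn, so the approach scales with
cluster count rather than edge count.
"""

import tempfile
from pathlib import Path

import seqspace as ss
from seqspace.layout import read_layout, write_layout

tmp = Path(tempfile.mkdtemp())
world = ss.make_world(seed=0)
store = ss.EdgeStore.from_edges(world.edges, tmp / "edges.tsv",
                                universe=[r.id for r in world.sequences])
hier = ss.components_multi(store, [80, 185])

layout = ss.build_layout(hier, min_size=5, seed=0)
write_layout(tmp / "layout.tsv", layout)
print(f"{len(layout.circles)} circles written to {tmp / 'layout.tsv'}")
for c in read_layout(tmp / "layout.tsv").circles[:5]:
    print(f"  {c.level:14s} {c.cluster_id:12s} r={c.radius:6.2f} "
          f"center=({c.x:7.2f},{c.y:7.2f}) parent={c.parent_id}")
# every child circle lies within 95% of its parent's radius, and within a
# sibling group area ratios equal cluster-size ratios exactly.

rows = ss.layout.annotate_layout(layout, hier, world.annotations)
mixed = sum(r["mixed"] for r in rows)
print(f"{mixed} of {len(rows)} circles contain more than one annotated function")
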