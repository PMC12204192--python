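"""Clustering-agreement metrics between cluster definitions.

Agreement between two partitions of the same sequences is quantified by the
adjusted Rand index (ARI) and adjusted mutual information (AMI), both
chance-corrected so that 0 means independent assignments and 1 means
perfect agreement regardless of cluster counts.  The scores themselves come
from scikit-learn (AMI normalized by the arithmetic mean of entropies); this
module contributes the id-universe alignment and the full cut-off-by-cut-off
sweep between two hierarchies.
"""

from __future__ import annotations

import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .components import ClusterHierarchy, Partition
from .errors import UniverseError


def _aligned_labels(p: Partition, q: Partition) -> tuple[list[str], list[str]]:
    if p.universe() != q.universe():
        raise UniverseError(
            f"partitions {p.level!r} and {q.level!r} cover different id universes")
    order = sorted(p.assignment)
    return p.labels(order), q.labels(order)


def ari(p: Partition, q: Partition) -> float:
    """Adjusted Rand index in [-1, 1]; label- and order-invariant."""
    a, b = _aligned_labels(p, q)
    return float(adjusted_rand_score(a, b))


def ami(p: Partition, q: Partition) -> float:
    """Adjusted mutual information (<= 1), arithmetic-mean normalization."""
    a, b = _aligned_labels(p, q)
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def agreement_sweep(hier_a: ClusterHierarchy, hier_b: ClusterHierarchy) -> pd.DataFrame:
    """ARI/AMI over the full grid of level pairs between two hierarchies.

    Returns a DataFrame with one row per (level_a, level_b) in deterministic
    order, carrying both scores and the cluster counts at each level.
    """
    rows = []
    for pa in hier_a.partitions:
        for pb in hier_b.partitions:
            rows.append({
                "level_a": pa.level,
                "level_b": pb.level,
                "ari": ari(pa, pb),
                "ami": ami(pa, pb),
                "n_clusters_a": pa.n_clusters,
                "n_clusters_b": pb.n_clusters,
            })
    return pd.DataFrame(rows)
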