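"""Even sampling of sequence space for phylogenetics.

Instead of collecting BLAST hits around a few anchor sequences (which
oversamples their immediate neighborhoods), one representative is drawn
from every SSN neighborhood whose size falls within a window, starting at a
base bitscore cut-off.  Oversized neighborhoods are recursively re-clustered
at higher cut-offs in fixed bitscore steps until they fall inside the
window or the maximum cut-off is reached; undersized neighborhoods are
skipped.  Representatives whose lengths fall outside a length window are
excluded (and logged) as potential outliers.  Optionally, only neighborhoods
that contain an anchor sequence at a coarse anchor cut-off are visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .components import Partition, components_multi
from .errors import CoverageError
from .embedding import EmbeddingMatrix
from .io import SequenceRecord
from .network import EdgeStore
from .representatives import RepresentativeChoice, hmm_representative, vector_representative


@dataclass
class SamplingSpec:
    """Parameters of the even-sampling walk over the cut-off ladder."""

    base_cutoff: float = 150.0
    step: float = 10.0
    max_cutoff: float = 400.0
    size_window: tuple[int, int] = (100, 1000)
    length_window: tuple[int, int] = (100, 300)
    anchor_ids: frozenset[str] | None = None
    anchor_level: float = 102.0
    method: str = "hmm"          # "hmm" | "fallback" | "vector"

    def __post_init__(self):
        if self.size_window[0] >= self.size_window[1]:
            raise ValueError("size window must satisfy min < max")
        if self.length_window[0] >= self.length_window[1]:
            raise ValueError("length window must satisfy min < max")
        if self.step <= 0 or self.base_cutoff > self.max_cutoff:
            raise ValueError("need step > 0 and base_cutoff <= max_cutoff")

    def ladder(self) -> list[float]:
        out = []
        c = self.base_cutoff
        while c <= self.max_cutoff + 1e-9:
            out.append(c)
            c += self.step
        return out


@dataclass
class SampleReport:
    """Chosen representatives plus skipped clusters with reasons."""

    chosen: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    @property
    def chosen_ids(self) -> list[str]:
        return [row["id"] for row in self.chosen]


def _pick_representative(
    members: Sequence[str],
    sequences: Mapping[str, SequenceRecord],
    vectors: EmbeddingMatrix | None,
    spec: SamplingSpec,
    cluster_id: str,
) -> RepresentativeChoice:
    if spec.method == "vector":
        if vectors is None:
            raise CoverageError("vector representative selection requires vectors")
        return vector_representative(sorted(members), vectors, cluster_id=cluster_id)
    engine = "hmmer" if spec.method == "hmm" else spec.method
    recs = [sequences[m] for m in sorted(members)]
    return hmm_representative(recs, engine=engine, cluster_id=cluster_id)


def even_sample(
    store: EdgeStore,
    spec: SamplingSpec,
    sequences: Mapping[str, SequenceRecord],
    vectors: EmbeddingMatrix | None = None,
    chunk_edges: int = 1_000_000,
) -> SampleReport:
    """One representative per size-window neighborhood across the cut-off ladder.

    Deterministic: clusters are visited in canonical (sorted) id order and
    each qualifying cluster contributes at most one representative.
    """
    cutoffs = spec.ladder()
    if spec.anchor_ids is not None:
        missing = spec.anchor_ids - store.node_ids
        if missing:
            raise CoverageError(f"anchors absent from universe: {sorted(missing)[:5]}")
        if spec.anchor_level >= spec.base_cutoff:
            raise ValueError("anchor_level must be below base_cutoff")
        all_cutoffs = [spec.anchor_level] + cutoffs
    else:
        all_cutoffs = cutoffs
    hier = components_multi(store, all_cutoffs, chunk_edges=chunk_edges)
    parts: list[Partition] = hier.partitions

    allowed: set[str] | None = None
    if spec.anchor_ids is not None:
        anchor_part = parts[0]
        parts = parts[1:]
        anchor_clusters = {anchor_part.assignment[a] for a in spec.anchor_ids}
        allowed = {sid for sid, cid in anchor_part.assignment.items() if cid in anchor_clusters}

    clusters_per_level = [p.clusters() for p in parts]
    report = SampleReport()
    lo, hi = spec.size_window
    len_lo, len_hi = spec.length_window

    def consider(level_idx: int, cluster_id: str, members: set[str]) -> None:
        size = len(members)
        cutoff = cutoffs[level_idx]
        if size < lo:
            report.skipped.append({"cluster": cluster_id, "cutoff": cutoff,
                                   "size": size, "reason": "too_small"})
            return
        if size > hi and level_idx + 1 < len(parts):
            fine = parts[level_idx + 1]
            children: dict[str, set[str]] = {}
            for sid in members:
                children.setdefault(fine.assignment[sid], set()).add(sid)
            for child_id in sorted(children):
                consider(level_idx + 1, child_id, children[child_id])
            return
        choice = _pick_representative(sorted(members), sequences, vectors, spec, cluster_id)
        rep_len = len(sequences[choice.representative])
        if not (len_lo <= rep_len <= len_hi):
            report.skipped.append({"cluster": cluster_id, "cutoff": cutoff,
                                   "size": size, "reason": "rep_length_out_of_window"})
            return
        row = {"id": choice.representative, "cluster": cluster_id,
               "cutoff": cutoff, "size": size}
        if size > hi:
            row["reason"] = "unresolved_at_max_cutoff"
        report.chosen.append(row)

    base_clusters = clusters_per_level[0]
    for cid in sorted(base_clusters):
        members = base_clusters[cid]
        if allowed is not None:
            if not members & allowed:
                continue
        consider(0, cid, members)
    return report


def coverage_compare(
    sample_a: set[str],
    sample_b: set[str],
    partition: Partition,
) -> dict[str, float]:
    """Fraction of one sample's clusters not covered by another sample.

    ``b_only_fraction`` is the fraction of sample-b ids whose cluster
    contains no sample-a id — the "novel cluster coverage" statistic of the
    even-sampling comparison.
    """
    clusters_a = {partition.assignment[s] for s in sample_a if s in partition.assignment}
    clusters_b = {partition.assignment[s] for s in sample_b if s in partition.assignment}
    b_only = [s for s in sample_b
              if s in partition.assignment and partition.assignment[s] not in clusters_a]
    return {
        "clusters_a": len(clusters_a),
        "clusters_b": len(clusters_b),
        "b_only_fraction": len(b_only) / len(sample_b) if sample_b else 0.0,
    }
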