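"""Resumable end-to-end pipeline: network -> cutoffs -> clustering -> layout -> reps -> sampling.

Each stage writes its outputs plus a small JSON manifest recording the
parameters and the SHA-256 hashes of its inputs and outputs.  Re-running a
stage whose manifest still matches its inputs is a no-op, which makes the
whole pipeline resumable and cheap to iterate on; corrupting or changing an
intermediate invalidates that stage and everything downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import agreement  # noqa: F401  (re-exported convenience)
from .components import ClusterHierarchy, components_multi
from .embedding import EmbeddingMatrix, fit_reduce
from .errors import SeqspaceError
from .io import read_fasta, write_cluster_map
from .layout import build_layout, write_layout
from .network import EdgeStore, percentile_cutoffs, sample_bitscores
from .representatives import hmm_representative, vector_representative
from .sampling import SamplingSpec, even_sample
from .vector_clustering import bisecting_kmeans, flatten, tree_to_linkage

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs, paths and per-stage parameters.

    ``stages`` lists the enabled stages in order; every random operation
    derives its seed from the single master ``seed``.
    """

    out_dir: str
    fasta: str
    m8: str
    vectors: str | None = None
    seed: int = 0
    evalue_max: float = 1e-3
    chunk_edges: int = 1_000_000
    percentiles: list[float] = field(default_factory=lambda: [10, 25, 50, 75, 90])
    max_bitscore_sample: int = 1_000_000
    reduce_dims: int = 30
    k_max: int = 100
    flatten_ks: list[int] = field(default_factory=lambda: [5, 10, 25])
    layout_min_size: int | None = None
    rep_method: str = "fallback"      # "hmm" | "fallback" | "vector"
    sampling: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: [
        "network", "cutoffs", "homology", "vector", "layout", "representatives"])

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SeqspaceError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("fasta", "m8"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise SeqspaceError(f"config path {name}={p!r} does not exist")
        if self.vectors is not None and not Path(self.vectors).exists():
            raise SeqspaceError(f"vectors path {self.vectors!r} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class _Stage:
    def __init__(self, out_dir: Path, name: str, params: dict, inputs: list[Path]):
        self.dir = out_dir / name
        self.name = name
        self.params = params
        self.inputs = [Path(p) for p in inputs]
        self.manifest_path = self.dir / "manifest.json"

    def fingerprint(self) -> dict:
        return {
            "stage": self.name,
            "params": self.params,
            "inputs": {str(p): _sha256(p) for p in self.inputs},
        }

    def is_cached(self) -> bool:
        if not self.manifest_path.exists():
            return False
        try:
            manifest = json.loads(self.manifest_path.read_text())
        except json.JSONDecodeError:
            return False
        fp = self.fingerprint()
        if manifest.get("params") != fp["params"] or manifest.get("inputs") != fp["inputs"]:
            return False
        for path, digest in manifest.get("outputs", {}).items():
            p = Path(path)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def finish(self, outputs: list[Path]) -> None:
        manifest = self.fingerprint()
        manifest["status"] = "completed"
        manifest["outputs"] = {str(p): _sha256(p) for p in outputs}
        self.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages, skipping those whose manifests are still valid.

    Returns the artifact directory.  A stage failure propagates with the
    stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    state: dict[str, object] = {}
    for stage_name in config.stages:
        runner = _STAGES.get(stage_name)
        if runner is None:
            raise SeqspaceError(f"unknown stage {stage_name!r}")
        try:
            runner(config, out, state)
        except SeqspaceError:
            raise
        except Exception as exc:
            raise SeqspaceError(f"stage {stage_name!r} failed: {exc}") from exc
    return out


def _load_hierarchy(out: Path) -> ClusterHierarchy:
    from .components import Partition
    from .io import read_cluster_map

    table = read_cluster_map(out / "homology" / "clusters.tsv")
    cutoffs = json.loads((out / "cutoffs" / "cutoffs.json").read_text())["thresholds"]
    levels = [f"bitscore:{c:g}" for c in cutoffs]
    return ClusterHierarchy(partitions=[Partition(l, table[l]) for l in levels])


def _stage_network(config: RunConfig, out: Path, state: dict) -> None:
    stage = _Stage(out, "network", {"evalue_max": config.evalue_max},
                   [Path(config.fasta), Path(config.m8)])
    stage.dir.mkdir(exist_ok=True)
    edges_path = stage.dir / "edges.tsv"
    universe_path = stage.dir / "universe.txt"
    if not stage.is_cached():
        records = read_fasta(config.fasta)
        store = EdgeStore.from_m8(config.m8, edges_path,
                                  universe=[r.id for r in records],
                                  evalue_max=config.evalue_max,
                                  chunk_edges=config.chunk_edges)
        universe_path.write_text("\n".join(sorted(store.node_ids)) + "\n")
        stage.finish([edges_path, universe_path])
    else:
        log.info("stage network cached; skipping")
    universe = universe_path.read_text().split()
    n_edges = sum(1 for _ in open(edges_path))
    state["store"] = EdgeStore(edges_path, n_edges, frozenset(universe))


def _stage_cutoffs(config: RunConfig, out: Path, state: dict) -> None:
    store: EdgeStore = state["store"]
    stage = _Stage(out, "cutoffs",
                   {"percentiles": config.percentiles, "seed": config.seed,
                    "max_sample": config.max_bitscore_sample},
                   [store.path])
    stage.dir.mkdir(exist_ok=True)
    path = stage.dir / "cutoffs.json"
    if not stage.is_cached():
        scores = sample_bitscores(store, max_sample=config.max_bitscore_sample, seed=config.seed)
        cutoffs = percentile_cutoffs(scores, config.percentiles)
        path.write_text(json.dumps({"thresholds": list(cutoffs.thresholds),
                                    "provenance": cutoffs.provenance}, indent=2))
        stage.finish([path])
    state["cutoffs"] = json.loads(path.read_text())["thresholds"]


def _stage_homology(config: RunConfig, out: Path, state: dict) -> None:
    store: EdgeStore = state["store"]
    stage = _Stage(out, "homology",
                   {"cutoffs": state["cutoffs"], "chunk_edges": config.chunk_edges},
                   [store.path])
    stage.dir.mkdir(exist_ok=True)
    clusters_path = stage.dir / "clusters.tsv"
    parents_path = stage.dir / "parents.tsv"
    if not stage.is_cached():
        hier = components_multi(store, state["cutoffs"], chunk_edges=config.chunk_edges)
        write_cluster_map(clusters_path, {p.level: p.assignment for p in hier.partitions})
        with open(parents_path, "w", newline="\n") as fh:
            fh.write("fine_level\tfine_cluster\tcoarse_cluster\n")
            for i, pm in enumerate(hier.parent_maps):
                level = hier.partitions[i + 1].level
                for fine in sorted(pm):
                    fh.write(f"{level}\t{fine}\t{pm[fine]}\n")
        stage.finish([clusters_path, parents_path])
        state["hierarchy"] = hier
    else:
        state["hierarchy"] = _load_hierarchy(out)


def _stage_vector(config: RunConfig, out: Path, state: dict) -> None:
    if config.vectors is None:
        log.info("no vectors configured; skipping vector stage")
        return
    stage = _Stage(out, "vector",
                   {"k_max": config.k_max, "flatten_ks": config.flatten_ks,
                    "reduce_dims": config.reduce_dims, "seed": config.seed},
                   [Path(config.vectors)])
    stage.dir.mkdir(exist_ok=True)
    path = stage.dir / "clusters.tsv"
    if not stage.is_cached():
        emb = EmbeddingMatrix.load(config.vectors)
        if emb.d > config.reduce_dims and emb.n > config.reduce_dims:
            _, emb = fit_reduce(emb, config.reduce_dims)
        tree = bisecting_kmeans(emb, min(config.k_max, emb.n), seed=config.seed)
        merge = tree_to_linkage(tree)
        parts = {}
        for k in sorted(set(config.flatten_ks)):
            if k <= merge.n_items:
                p = flatten(merge, k)
                parts[p.level] = p.assignment
        write_cluster_map(path, parts)
        stage.finish([path])


def _stage_layout(config: RunConfig, out: Path, state: dict) -> None:
    stage = _Stage(out, "layout",
                   {"min_size": config.layout_min_size, "seed": config.seed},
                   [out / "homology" / "clusters.tsv"])
    stage.dir.mkdir(exist_ok=True)
    path = stage.dir / "layout.tsv"
    if not stage.is_cached():
        layout = build_layout(state["hierarchy"], min_size=config.layout_min_size,
                              seed=config.seed)
        write_layout(path, layout)
        stage.finish([path])


def _stage_representatives(config: RunConfig, out: Path, state: dict) -> None:
    stage = _Stage(out, "representatives",
                   {"method": config.rep_method},
                   [out / "homology" / "clusters.tsv"])
    stage.dir.mkdir(exist_ok=True)
    path = stage.dir / "reps.tsv"
    if not stage.is_cached():
        hier: ClusterHierarchy = state["hierarchy"]
        finest = hier.partitions[-1]
        records = {r.id: r for r in read_fasta(config.fasta)}
        vectors = EmbeddingMatrix.load(config.vectors) if config.vectors else None
        rows = []
        for cid, members in sorted(finest.clusters().items()):
            if config.rep_method == "vector":
                choice = vector_representative(sorted(members), vectors, cluster_id=cid)
            else:
                engine = "hmmer" if config.rep_method == "hmm" else "fallback"
                choice = hmm_representative([records[m] for m in sorted(members)],
                                            engine=engine, cluster_id=cid)
            rows.append(choice)
        with open(path, "w", newline="\n") as fh:
            fh.write("cluster_id\trepresentative\tmethod\tscore\n")
            for c in rows:
                fh.write(f"{c.cluster_id}\t{c.representative}\t{c.method}\t{c.score:.6g}\n")
        stage.finish([path])


def _stage_sample(config: RunConfig, out: Path, state: dict) -> None:
    stage = _Stage(out, "sample", {"sampling": config.sampling},
                   [state["store"].path])
    stage.dir.mkdir(exist_ok=True)
    path = stage.dir / "sample.tsv"
    if not stage.is_cached():
        spec_kwargs = dict(config.sampling)
        if "anchor_ids" in spec_kwargs and spec_kwargs["anchor_ids"] is not None:
            spec_kwargs["anchor_ids"] = frozenset(spec_kwargs["anchor_ids"])
        for key in ("size_window", "length_window"):
            if key in spec_kwargs:
                spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = SamplingSpec(**spec_kwargs)
        records = {r.id: r for r in read_fasta(config.fasta)}
        vectors = EmbeddingMatrix.load(config.vectors) if config.vectors else None
        report = even_sample(state["store"], spec, records, vectors,
                             chunk_edges=config.chunk_edges)
        with open(path, "w", newline="\n") as fh:
            fh.write("id\tcluster\tcutoff\tsize\treason\n")
            for row in report.chosen:
                fh.write(f"{row['id']}\t{row['cluster']}\t{row['cutoff']:g}\t"
                         f"{row['size']}\t{row.get('reason', '')}\n")
        stage.finish([path])


_STAGES = {
    "network": _stage_network,
    "cutoffs": _stage_cutoffs,
    "homology": _stage_homology,
    "vector": _stage_vector,
    "layout": _stage_layout,
    "representatives": _stage_representatives,
    "sample": _stage_sample,
}
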