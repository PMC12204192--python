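"""Build or ingest the all-vs-all homology edge set and choose bitscore cut-offs.

The sequence similarity network (SSN) is a weighted undirected graph whose
nodes are sequences and whose edges carry pairwise-alignment bitscores.  The
edge set lives on disk as a normalized tab-separated file so that networks
far larger than RAM can be processed by streaming.  Cut-offs for the
hierarchy are chosen from empirical percentiles of the bitscore
distribution, which is itself estimated from a reservoir sample so the edge
file is only ever read once.
"""

from __future__ import annotations

import logging
import random
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyInputError, ExternalToolError, ToolNotFound
from .io import HomologyEdge, normalize_edges, read_fasta, stream_m8

log = logging.getLogger(__name__)


@dataclass
class EdgeStore:
    """Normalized homology edges on disk plus the full node universe.

    The node universe includes edge-less sequences, which must survive as
    singleton clusters at every cut-off.
    """

    path: Path
    n_edges: int
    node_ids: frozenset[str]

    def iter_edges(self, chunk_edges: int = 1_000_000) -> Iterator[list[tuple[str, str, float]]]:
        """Yield batches of (id_a, id_b, bitscore), at most ``chunk_edges`` each."""
        batch: list[tuple[str, str, float]] = []
        with open(self.path) as fh:
            for line in fh:
                a, b, s = line.rstrip("\n").split("\t")
                batch.append((a, b, float(s)))
                if len(batch) >= chunk_edges:
                    yield batch
                    batch = []
        if batch:
            yield batch

    def iter_bitscores(self) -> Iterator[float]:
        with open(self.path) as fh:
            for line in fh:
                yield float(line.rsplit("\t", 1)[1])

    @classmethod
    def from_m8(
        cls,
        m8_path: str | Path,
        out_path: str | Path,
        universe: Sequence[str] | None = None,
        evalue_max: float = 1e-3,
        chunk_edges: int = 1_000_000,
    ) -> "EdgeStore":
        """Normalize an m8 hit file into an edge store.

        Reciprocal hits are merged keeping the max bitscore; self-hits and
        hits failing the E-value filter are dropped.  ``universe`` extends
        the node set with sequences that have no surviving edges.
        """
        best: dict[tuple[str, str], float] = {}
        for batch in stream_m8(m8_path, chunk_edges=chunk_edges):
            for e in normalize_edges(batch, evalue_max=evalue_max):
                key = e.pair()
                if e.bitscore > best.get(key, -1.0):
                    best[key] = e.bitscore
        out_path = Path(out_path)
        nodes: set[str] = set(universe) if universe is not None else set()
        with open(out_path, "w", newline="\n") as fh:
            for (a, b) in sorted(best):
                fh.write(f"{a}\t{b}\t{best[(a, b)]:g}\n")
                nodes.add(a)
                nodes.add(b)
        return cls(path=out_path, n_edges=len(best), node_ids=frozenset(nodes))

    @classmethod
    def from_edges(
        cls,
        edges: Sequence[HomologyEdge] | Sequence[tuple[str, str, float]],
        out_path: str | Path,
        universe: Sequence[str] | None = None,
    ) -> "EdgeStore":
        """Write an in-memory edge list (already normalized) to a store."""
        out_path = Path(out_path)
        nodes: set[str] = set(universe) if universe is not None else set()
        rows: list[tuple[str, str, float]] = []
        for e in edges:
            a, b, s = (e.query_id, e.target_id, e.bitscore) if isinstance(e, HomologyEdge) else e
            if a > b:
                a, b = b, a
            rows.append((a, b, s))
            nodes.add(a)
            nodes.add(b)
        rows.sort()
        with open(out_path, "w", newline="\n") as fh:
            for a, b, s in rows:
                fh.write(f"{a}\t{b}\t{s:g}\n")
        return cls(path=out_path, n_edges=len(rows), node_ids=frozenset(nodes))


def run_allvsall_search(
    fasta: str | Path,
    out_dir: str | Path,
    max_hits: int = 1000,
    engine: str = "mmseqs",
    m8_path: str | Path | None = None,
    evalue_max: float = 1e-3,
) -> EdgeStore:
    """All-by-all pairwise local alignment of a FASTA file into an EdgeStore.

    ``engine="mmseqs"`` invokes MMSeqs2 easy-search on default settings with
    an increased maximum hit count; ``engine="blast"`` uses makeblastdb +
    blastp with tabular output.  If ``m8_path`` is supplied the external
    tool is skipped entirely and the precomputed hits are ingested.

    Raises :class:`ToolNotFound` when the executable is absent and
    :class:`ExternalToolError` (with captured stderr) on non-zero exit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(fasta)
    universe = [r.id for r in records]
    store_path = out_dir / "edges.tsv"

    if m8_path is not None:
        return EdgeStore.from_m8(m8_path, store_path, universe=universe, evalue_max=evalue_max)

    if engine == "mmseqs":
        exe = shutil.which("mmseqs")
        if exe is None:
            raise ToolNotFound("mmseqs executable not found on PATH")
        hits = out_dir / "hits.m8"
        with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
            cmd = [exe, "easy-search", str(fasta), str(fasta), str(hits), tmp,
                   "--max-seqs", str(max_hits)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(f"mmseqs exited {proc.returncode}", stderr=proc.stderr)
    elif engine == "blast":
        for tool in ("makeblastdb", "blastp"):
            if shutil.which(tool) is None:
                raise ToolNotFound(f"{tool} executable not found on PATH")
        hits = out_dir / "hits.m8"
        with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
            db = str(Path(tmp) / "db")
            proc = subprocess.run(
                ["makeblastdb", "-in", str(fasta), "-dbtype", "prot", "-out", db],
                capture_output=True, text=True)
            if proc.returncode != 0:
                raise ExternalToolError(f"makeblastdb exited {proc.returncode}", stderr=proc.stderr)
            proc = subprocess.run(
                ["blastp", "-query", str(fasta), "-db", db, "-outfmt", "6",
                 "-max_target_seqs", str(max_hits), "-out", str(hits)],
                capture_output=True, text=True)
            if proc.returncode != 0:
                raise ExternalToolError(f"blastp exited {proc.returncode}", stderr=proc.stderr)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return EdgeStore.from_m8(hits, store_path, universe=universe, evalue_max=evalue_max)


def sample_bitscores(store: EdgeStore, max_sample: int = 1_000_000, seed: int = 0) -> list[float]:
    """Uniform reservoir sample of up to ``max_sample`` bitscores from a store.

    When the edge count is at most ``max_sample`` the full population
    multiset is returned; otherwise a single-pass reservoir sample of
    exactly ``max_sample`` values, reproducible under ``seed``.
    """
    if store.n_edges == 0:
        raise EmptyInputError("edge store is empty")
    rng = random.Random(seed)
    reservoir: list[float] = []
    for i, score in enumerate(store.iter_bitscores()):
        if i < max_sample:
            reservoir.append(score)
        else:
            j = rng.randrange(i + 1)
            if j < max_sample:
                reservoir[j] = score
    return reservoir


@dataclass(frozen=True)
class CutoffSet:
    """Ordered, strictly increasing bitscore thresholds with provenance."""

    thresholds: tuple[int, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self):
        return len(self.thresholds)


def percentile_cutoffs(
    bitscores: Sequence[float],
    percentiles: Sequence[float] = (10, 25, 50, 75, 90),
) -> CutoffSet:
    """Empirical percentile bitscore thresholds.

    Quantiles use linear interpolation between order statistics (the common
    "type 7" rule) and are rounded half-up to integers; duplicate thresholds
    collapse with a logged warning.
    """
    if len(bitscores) == 0:
        raise EmptyInputError("no bitscores to take percentiles of")
    ps = list(percentiles)
    if any(not (0 < p < 100) for p in ps) or any(a >= b for a, b in zip(ps, ps[1:])):
        raise ValueError("percentiles must be strictly increasing and within (0, 100)")
    qs = np.percentile(np.asarray(bitscores, dtype=float), ps, method="linear")
    rounded = [int(np.floor(q + 0.5)) for q in qs]
    thresholds: list[int] = []
    for t in rounded:
        if thresholds and t == thresholds[-1]:
            log.warning("collapsing duplicate cutoff %d", t)
            continue
        thresholds.append(t)
    return CutoffSet(
        thresholds=tuple(thresholds),
        provenance={"percentiles": ps, "sample_size": len(bitscores)},
    )
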