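"""Readers and writers for every external representation the pipeline touches.

Formats handled here: FASTA (via Biopython), the 12-column BLAST/MMSeqs
tabular hit format ("m8"), tab-separated cluster-map tables, Newick trees
(via scikit-bio) and iTOL annotation dataset files.  All text output is
UTF-8 with Unix newlines and deterministic (sorted) row order.
"""

from __future__ import annotations

import hashlib
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from skbio import TreeNode

from .errors import DuplicateIdError, EmptyInputError, FormatError

#: residues accepted in a SequenceRecord: the 20 amino acids plus ambiguity
#: codes and the gap character.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU" + "-")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a unique whitespace-free id."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if len(self.residues) < 1:
            raise FormatError(f"empty sequence for id {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HomologyEdge:
    """An undirected homology hit between two sequences, weighted by bitscore."""

    query_id: str
    target_id: str
    bitscore: float
    evalue: float | None = None

    def pair(self) -> tuple[str, str]:
        """Unordered pair key, lexicographically smaller id first."""
        a, b = self.query_id, self.target_id
        return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an ordered list of records from a FASTA file.

    Duplicate ids raise :class:`DuplicateIdError`; an empty file raises
    :class:`EmptyInputError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, description=desc, residues=str(rec.seq).upper()))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord]) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# m8 tabular hits


def stream_m8(path: str | Path, chunk_edges: int = 1_000_000) -> Iterator[list[HomologyEdge]]:
    """Stream a BLAST/MMSeqs tabular hit file in batches of ``chunk_edges``.

    The 12-column dialect is expected (query, target, fident, alnlen,
    mismatch, gapopen, qstart, qend, tstart, tend, evalue, bits); extra
    trailing columns are tolerated and ignored.  Bitscore comes from column
    12 and E-value from column 11.  A line with fewer than 12 columns raises
    :class:`FormatError` with its 1-based line number.
    """
    if chunk_edges < 1:
        raise ValueError("chunk_edges must be >= 1")
    batch: list[HomologyEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"expected >= 12 tab-separated columns, got {len(cols)}", line=lineno)
            try:
                edge = HomologyEdge(
                    query_id=cols[0],
                    target_id=cols[1],
                    bitscore=float(cols[11]),
                    evalue=float(cols[10]),
                )
            except ValueError as exc:
                raise FormatError(f"unparseable numeric field: {exc}", line=lineno) from exc
            batch.append(edge)
            if len(batch) >= chunk_edges:
                yield batch
                batch = []
    if batch:
        yield batch


def write_m8(path: str | Path, edges: Iterable[HomologyEdge]) -> None:
    """Write edges as minimal 12-column m8 lines (placeholder alignment fields)."""
    with open(path, "w", newline="\n") as fh:
        for e in edges:
            ev = e.evalue if e.evalue is not None else 0.0
            fh.write(
                f"{e.query_id}\t{e.target_id}\t1.000\t0\t0\t0\t0\t0\t0\t0\t{ev:g}\t{e.bitscore:g}\n"
            )


def normalize_edges(edges: Iterable[HomologyEdge], evalue_max: float = 1e-3) -> list[HomologyEdge]:
    """Canonicalize a batch of homology hits.

    Self-hits are removed, hits with E-value >= ``evalue_max`` are removed,
    and reciprocal/duplicate hits for the same unordered pair are merged
    keeping the maximum bitscore.  Each surviving pair is stored with the
    lexicographically smaller id first; output is sorted by pair, making
    the operation idempotent and deterministic.
    """
    best: dict[tuple[str, str], HomologyEdge] = {}
    for e in edges:
        if e.query_id == e.target_id:
            continue
        if e.evalue is not None and e.evalue >= evalue_max:
            continue
        a, b = e.pair()
        key = (a, b)
        prev = best.get(key)
        if prev is None or e.bitscore > prev.bitscore:
            best[key] = HomologyEdge(a, b, e.bitscore, e.evalue)
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# cluster maps

CLUSTER_MAP_HEADER = "sequence_id\tlevel_label\tcluster_id"


def write_cluster_map(path: str | Path, assignment: Mapping[str, Mapping[str, str]]) -> None:
    """Write an id -> cluster table covering one or more levels.

    ``assignment`` maps level label -> {sequence id -> cluster id}.  Rows are
    sorted by (level, id) so output is deterministic.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write(CLUSTER_MAP_HEADER + "\n")
        for level in sorted(assignment):
            table = assignment[level]
            for sid in sorted(table):
                fh.write(f"{sid}\t{level}\t{table[sid]}\n")


def read_cluster_map(path: str | Path, levels: Sequence[str] | None = None) -> dict[str, dict[str, str]]:
    """Inverse of :func:`write_cluster_map`.

    If ``levels`` is given, a row with a level label outside it raises
    :class:`FormatError`.  Duplicate (id, level) rows raise
    :class:`DuplicateIdError`.
    """
    known = set(levels) if levels is not None else None
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != CLUSTER_MAP_HEADER:
            raise FormatError(f"bad cluster-map header {header!r}", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError("expected 3 columns", line=lineno)
            sid, level, cid = cols
            if known is not None and level not in known:
                raise FormatError(f"unknown level label {level!r}", line=lineno)
            table = out.setdefault(level, {})
            if sid in table:
                raise DuplicateIdError(f"duplicate (id, level) row: ({sid}, {level})")
            table[sid] = cid
    return out


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string with branch lengths."""
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string; malformed input raises :class:`FormatError`."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # skbio sniffs before raising
            tree = TreeNode.read(_stdio.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"unparseable Newick: {exc}") from exc
    return tree


# ---------------------------------------------------------------------------
# iTOL annotation datasets


def category_color(category: str) -> str:
    """Deterministic hex color for an annotation category (hash-seeded)."""
    digest = hashlib.md5(category.encode()).hexdigest()
    # keep colors reasonably saturated by mixing with a mid-grey floor
    r, g, b = (int(digest[i:i + 2], 16) for i in (0, 2, 4))
    r, g, b = (60 + v * 195 // 255 for v in (r, g, b))
    return f"#{r:02x}{g:02x}{b:02x}"


def write_itol_annotations(
    path: str | Path,
    annotations: Mapping[str, str],
    dataset_label: str = "function",
) -> Path:
    """Write an iTOL DATASET_COLORSTRIP file coloring leaves by category.

    Colors are assigned deterministically per category, so the same input
    always produces byte-identical output.
    """
    path = Path(path)
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#888888",
        "LEGEND_TITLE\t" + dataset_label,
    ]
    categories = sorted(set(annotations.values()))
    if categories:
        lines.append("LEGEND_SHAPES\t" + "\t".join("1" for _ in categories))
        lines.append("LEGEND_COLORS\t" + "\t".join(category_color(c) for c in categories))
        lines.append("LEGEND_LABELS\t" + "\t".join(categories))
    lines.append("DATA")
    for leaf in sorted(annotations):
        cat = annotations[leaf]
        lines.append(f"{leaf}\t{category_color(cat)}\t{cat}")
    path.write_text("\n".join(lines) + "\n", newline="\n")
    return path


# ---------------------------------------------------------------------------
# annotation tables


@dataclass
class AnnotationTable:
    """Per-sequence key/value annotations (function, taxon genus, ...)."""

    rows: dict[str, dict[str, str]] = field(default_factory=dict)

    def get(self, sid: str, key: str) -> str | None:
        return self.rows.get(sid, {}).get(key)

    def ids(self) -> set[str]:
        return set(self.rows)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a tab-separated annotation table with a header row (first column = id)."""
    table = AnnotationTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError("annotation table needs an id column plus >= 1 key column", line=1)
        keys = header[1:]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            sid = cols[0]
            if sid in table.rows:
                raise DuplicateIdError(f"duplicate annotation id {sid!r}")
            table.rows[sid] = {k: v for k, v in zip(keys, cols[1:]) if v != ""}
    return table


def write_annotation_table(path: str | Path, table: AnnotationTable) -> None:
    keys = sorted({k for row in table.rows.values() for k in row})
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(["sequence_id"] + keys) + "\n")
        for sid in sorted(table.rows):
            row = table.rows[sid]
            fh.write("\t".join([sid] + [row.get(k, "") for k in keys]) + "\n")
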