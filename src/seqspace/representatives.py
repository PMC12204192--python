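"""Representative selection from sequence clusters, and cluster-quality metrics.

Two selection routes:

* **Profile-HMM**: align the cluster members, build a profile from the MSA,
  score every member against the profile, and pick the best scorer.  The
  profile engine is HMMER3 (through pyhmmer); a pure-Python per-column
  log-odds profile scorer is also provided so the selection logic is
  testable and usable without the HMMER machinery.  Scores from the two
  engines are on different scales and are never mixed in one report.

* **Vector centroid**: average the members' embedding vectors and pick the
  member closest (Euclidean) to the mean.

Representativeness is evaluated with global pairwise sequence identity
(Needleman-Wunsch, BLOSUM62, affine gaps 11/1; identity = identical aligned
positions / alignment length including gap columns): how much closer the
representative is to the members than random pairs are to each other
(delta_id), the representative's percentile rank of median identity within
the cluster, and its length deviation from the cluster median.
"""

from __future__ import annotations

import shutil
import statistics
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .embedding import EmbeddingMatrix
from .errors import CoverageError, EmptyInputError, ToolNotFound
from .io import AnnotationTable, SequenceRecord, read_fasta, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RepresentativeChoice:
    cluster_id: str
    representative: str
    method: str          # "hmm" | "fallback" | "vector"
    score: float         # HMM bitscore, profile log-odds, or -Euclidean distance


# ---------------------------------------------------------------------------
# global percent identity


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _sanitize(residues: str) -> str:
    # selenocysteine and gaps are outside BLOSUM62's alphabet
    return residues.replace("U", "X").replace("-", "")


def global_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Global percent identity between two sequences.

    Needleman-Wunsch with BLOSUM62 and affine gap penalties (open 11,
    extend 1); identity is the fraction of alignment columns (terminal gap
    columns included) where the two residues are identical, times 100.
    Symmetric by construction.
    """
    sa = _sanitize(a.residues if isinstance(a, SequenceRecord) else a)
    sb = _sanitize(b.residues if isinstance(b, SequenceRecord) else b)
    if not sa or not sb:
        raise EmptyInputError("cannot align empty sequences")
    if sa > sb:  # canonical order => symmetry even among tied optima
        sa, sb = sb, sa
    if sa == sb:
        return 100.0
    aln = _aligner().align(sa, sb)[0]
    top, bot = aln[0], aln[1]
    matches = sum(1 for x, y in zip(top, bot) if x == y and x != "-")
    return 100.0 * matches / aln.length


# ---------------------------------------------------------------------------
# profile models


@dataclass
class ProfileModel:
    """Per-column amino-acid log-odds over the match columns of an MSA.

    Match columns are MSA columns with < 50% gaps; emission probabilities
    use a Laplace pseudocount of 1 against a uniform background of 1/20.
    """

    match_columns: list[int]
    log_odds: list[dict[str, float]]   # one dict per match column

    def score(self, aligned_row: str) -> float:
        """Sum of match-column log-odds for one aligned member (gaps score 0)."""
        total = 0.0
        for col, lo in zip(self.match_columns, self.log_odds):
            total += lo.get(aligned_row[col], 0.0)
        return total


def build_profile(msa_rows: Sequence[str], gap_fraction: float = 0.5, pseudocount: float = 1.0) -> ProfileModel:
    if not msa_rows:
        raise EmptyInputError("empty MSA")
    width = len(msa_rows[0])
    if any(len(r) != width for r in msa_rows):
        raise ValueError("MSA rows must have equal length")
    n = len(msa_rows)
    match_columns: list[int] = []
    log_odds: list[dict[str, float]] = []
    background = 1.0 / len(AA20)
    for col in range(width):
        column = [row[col] for row in msa_rows]
        gaps = sum(1 for c in column if c == "-")
        if gaps / n >= gap_fraction:
            continue
        counts = {aa: pseudocount for aa in AA20}
        total = pseudocount * len(AA20)
        for c in column:
            if c in counts:
                counts[c] += 1.0
                total += 1.0
        match_columns.append(col)
        log_odds.append({aa: float(np.log(counts[aa] / total / background)) for aa in AA20})
    return ProfileModel(match_columns=match_columns, log_odds=log_odds)


# ---------------------------------------------------------------------------
# MSA construction


def align_with_mafft(members: Sequence[SequenceRecord]) -> list[str]:
    """MSA of the members via mafft (default settings); rows in member order."""
    exe = shutil.which("mafft")
    if exe is None:
        raise ToolNotFound("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(inp, members)
        proc = subprocess.run([exe, "--auto", "--quiet", "--anysymbol", str(inp)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise ToolNotFound(f"mafft failed: {proc.stderr[:500]}")
        out = Path(tmp) / "out.fasta"
        out.write_text(proc.stdout)
        aligned = {r.id: r.residues.upper() for r in read_fasta(out)}
    return [aligned[m.id] for m in members]


def _cluster_msa(members: Sequence[SequenceRecord], msa: Sequence[str] | None) -> list[str]:
    if msa is not None:
        if len(msa) != len(members):
            raise ValueError("provided MSA must have one row per member")
        return list(msa)
    lengths = {len(m.residues) for m in members}
    if len(lengths) == 1:
        return [m.residues for m in members]  # equal lengths: treat as aligned
    return align_with_mafft(members)


# ---------------------------------------------------------------------------
# selection


def hmm_representative(
    members: Sequence[SequenceRecord],
    engine: str = "hmmer",
    cluster_id: str = "",
    msa: Sequence[str] | None = None,
) -> RepresentativeChoice:
    """Pick the member scoring highest against the cluster's own profile.

    ``engine="hmmer"`` (alias ``"external"``) builds an HMMER3 profile from
    the MSA with pyhmmer and scores members with the HMMER pipeline;
    ``engine="fallback"`` uses the pure per-column log-odds profile.
    Ties break toward the smaller id.  Singletons represent themselves with
    score 0.
    """
    if not members:
        raise EmptyInputError("empty cluster")
    if len(members) == 1:
        return RepresentativeChoice(cluster_id, members[0].id, "hmm", 0.0)
    rows = _cluster_msa(members, msa)
    if engine in ("hmmer", "external"):
        scores = _score_with_hmmer(members, rows)
        method = "hmm"
    elif engine == "fallback":
        profile = build_profile(rows)
        scores = {m.id: profile.score(row) for m, row in zip(members, rows)}
        method = "fallback"
    else:
        raise ValueError(f"unknown engine {engine!r}")
    best = max(sorted(scores), key=lambda sid: scores[sid])
    return RepresentativeChoice(cluster_id, best, method, scores[best])


def _score_with_hmmer(members: Sequence[SequenceRecord], rows: Sequence[str]) -> dict[str, float]:
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    texts = [
        pyhmmer.easel.TextSequence(name=m.id.encode(), sequence=row)
        for m, row in zip(members, rows)
    ]
    msa = pyhmmer.easel.TextMSA(name=b"cluster", sequences=texts).digitize(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    builder = pyhmmer.plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(msa, background)
    pipeline = pyhmmer.plan7.Pipeline(alphabet, background=background, E=1e6, bias_filter=False)
    block = pyhmmer.easel.DigitalSequenceBlock(alphabet, [
        pyhmmer.easel.TextSequence(name=m.id.encode(), sequence=_sanitize(m.residues)).digitize(alphabet)
        for m in members
    ])
    hits = pipeline.search_hmm(hmm, block)
    scores = {m.id: float("-inf") for m in members}
    for hit in hits:
        name = hit.name if isinstance(hit.name, str) else hit.name.decode()
        scores[name] = float(hit.score)
    return scores


def vector_representative(
    member_ids: Sequence[str],
    vectors: EmbeddingMatrix,
    cluster_id: str = "",
) -> RepresentativeChoice:
    """Pick the member whose vector is closest (Euclidean) to the cluster mean."""
    if not member_ids:
        raise EmptyInputError("empty cluster")
    missing = [m for m in member_ids if m not in set(vectors.ids)]
    if missing:
        raise CoverageError(f"members without vectors: {missing[:5]}")
    ordered = sorted(member_ids)
    X = vectors.X[vectors.index_of(ordered)]
    mean = X.mean(axis=0)
    dist = np.linalg.norm(X - mean, axis=1)
    best = int(np.argmin(dist))  # argmin takes the first of ties; ids sorted => smaller id
    return RepresentativeChoice(cluster_id, ordered[best], "vector", -float(dist[best]))


# ---------------------------------------------------------------------------
# evaluation


def _pairwise_identity(members: Sequence[SequenceRecord]) -> np.ndarray:
    m = len(members)
    pid = np.full((m, m), 100.0)
    for i in range(m):
        for j in range(i + 1, m):
            pid[i, j] = pid[j, i] = global_identity(members[i], members[j])
    return pid


def evaluate_representative(
    members: Sequence[SequenceRecord],
    choice: RepresentativeChoice,
    sample_pairs: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """How well a chosen representative stands for its cluster.

    Returns ``delta_id`` (median %ID of members to the representative minus
    the median %ID of seeded random member pairs, capped at
    ``sample_pairs``), ``rank`` (percentile rank in [0, 1] of the
    representative's median %ID among all members' median %IDs; 1 = most
    central) and ``length_delta`` (representative length minus the median
    member length).
    """
    if len(members) < 2:
        raise EmptyInputError("evaluation needs a cluster of >= 2 members")
    ids = [m.id for m in members]
    rep_idx = ids.index(choice.representative)
    pid = _pairwise_identity(members)
    m = len(members)
    off_diag = ~np.eye(m, dtype=bool)
    member_medians = np.array([np.median(pid[i][off_diag[i]]) for i in range(m)])
    rep_median = member_medians[rep_idx]

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(m, k=1)
    all_pairs = np.c_[iu[0], iu[1]]
    if len(all_pairs) > sample_pairs:
        sel = rng.choice(len(all_pairs), size=sample_pairs, replace=False)
        all_pairs = all_pairs[sel]
    random_median = float(np.median(pid[all_pairs[:, 0], all_pairs[:, 1]]))

    rank = float(np.mean(member_medians <= rep_median))
    length_delta = float(len(members[rep_idx]) - statistics.median(len(x) for x in members))
    return {
        "delta_id": float(rep_median - random_median),
        "rank": rank,
        "length_delta": length_delta,
    }


def cluster_properties(
    partition_clusters: Mapping[str, set[str]],
    sequences: Mapping[str, SequenceRecord],
    annotations: AnnotationTable | None = None,
    min_size: int = 5,
    sample_pairs: int = 30,
    seed: int = 0,
    taxon_key: str = "taxon_genus",
) -> pd.DataFrame:
    """Size, within/between global %ID and genus diversity per cluster.

    Only clusters with at least ``min_size`` members are considered.
    Within- and between-cluster identities are medians over seeded
    subsamples of at most ``sample_pairs`` pairs each (full pairwise is
    quadratic).  Genus diversity counts distinct genus annotations among
    members (0 for unannotated clusters).
    """
    rng = np.random.default_rng(seed)
    eligible = {cid: sorted(m) for cid, m in partition_clusters.items() if len(m) >= min_size}
    all_ids = sorted({sid for m in eligible.values() for sid in m})
    rows = []
    for cid in sorted(eligible):
        members = eligible[cid]
        within: list[float] = []
        for _ in range(min(sample_pairs, len(members) * (len(members) - 1) // 2)):
            i, j = rng.choice(len(members), size=2, replace=False)
            within.append(global_identity(sequences[members[i]], sequences[members[j]]))
        member_set = set(members)
        outside = [sid for sid in all_ids if sid not in member_set]
        between: list[float] = []
        if outside:
            for _ in range(sample_pairs):
                a = members[rng.integers(len(members))]
                b = outside[rng.integers(len(outside))]
                between.append(global_identity(sequences[a], sequences[b]))
        genera = set()
        if annotations is not None:
            genera = {g for g in (annotations.get(m, taxon_key) for m in members) if g}
        rows.append({
            "cluster": cid,
            "size": len(members),
            "within_id_median": float(np.median(within)) if within else float("nan"),
            "between_id_median": float(np.median(between)) if between else float("nan"),
            "n_genera": len(genera),
        })
    return pd.DataFrame(rows)
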