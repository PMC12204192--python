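"""Seeded synthetic worlds: planted superfamily/family structure for every module.

A planted world emulates the hierarchical organization of a protein
superfamily: superfamily ancestors give rise to family center sequences by
point mutation at a high rate, and family members derive from their center
at a low rate.  Pairwise homology edges carry bitscores drawn from two
separable bands — a high band for within-family pairs and an intermediate
band for cross-family pairs inside the same superfamily — while
cross-superfamily pairs have no edge at all (emulating the E-value filter
of a real search).  Embedding vectors with matching two-level structure
come from :func:`seqspace.embedding.synth_embeddings`, and genus labels are
drawn per family from a small pool.  Everything is reproducible from
(parameters, seed) alone.

Band draws are truncated normals (clipped at three standard deviations and
at zero), so the separability precondition guarantees that a threshold
between the bands recovers the planted partition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .components import Partition
from .embedding import EmbeddingMatrix, synth_embeddings
from .errors import ParameterError
from .io import AnnotationTable, HomologyEdge, SequenceRecord, write_annotation_table, write_cluster_map, write_fasta, write_m8
from .representatives import AA20

GENUS_POOL = (
    "Bacillus", "Escherichia", "Pseudomonas", "Streptomyces",
    "Mycobacterium", "Vibrio", "Synechocystis", "Thermus",
)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        choices = [a for a in AA20 if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _band_draw(mu: float, sd: float, rng: np.random.Generator) -> float:
    x = float(np.clip(rng.normal(mu, sd), mu - 3 * sd, mu + 3 * sd))
    return max(0.0, x)


@dataclass
class PlantedWorld:
    """Sequences, truth partitions, edges, vectors and annotations, all consistent."""

    sequences: list[SequenceRecord]
    superfamily_partition: Partition
    family_partition: Partition
    edges: list[HomologyEdge]
    vectors: EmbeddingMatrix
    annotations: AnnotationTable
    seed: int
    params: dict = field(default_factory=dict)

    def sequence_map(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.sequences}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit FASTA + m8 + vectors + truth tables into a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "sequences.fasta",
            "m8": out / "hits.m8",
            "vectors": out / "vectors.npz",
            "truth": out / "truth_clusters.tsv",
            "annotations": out / "annotations.tsv",
        }
        write_fasta(paths["fasta"], self.sequences)
        write_m8(paths["m8"], self.edges)
        self.vectors.save(out / "vectors")
        write_cluster_map(paths["truth"], {
            self.superfamily_partition.level: self.superfamily_partition.assignment,
            self.family_partition.level: self.family_partition.assignment,
        })
        write_annotation_table(paths["annotations"], self.annotations)
        return paths


def make_world(
    n_super: int = 3,
    fam_per_super: int = 3,
    members_per_fam: int = 30,
    seq_len_range: tuple[int, int] = (120, 240),
    mut_rate_within: float = 0.05,
    mut_rate_between: float = 0.30,
    seed: int = 0,
    within_band: tuple[float, float] = (250.0, 10.0),
    between_band: tuple[float, float] = (120.0, 10.0),
    cross_family_fraction: float = 0.1,
    embed_dim: int = 30,
    sep_super: float = 100.0,
    sep_fam: float = 10.0,
    noise_sd: float = 1.0,
) -> PlantedWorld:
    """Generate a fully consistent planted world (see module docstring).

    ``mut_rate_within`` must be below ``mut_rate_between`` so families are
    tighter than superfamilies; the two bitscore bands must be separable at
    three standard deviations.
    """
    if mut_rate_within >= mut_rate_between:
        raise ParameterError("mut_rate_within must be < mut_rate_between")
    wmu, wsd = within_band
    bmu, bsd = between_band
    if wmu - 3 * wsd <= bmu + 3 * bsd:
        raise ParameterError("within and between bitscore bands must be separable")
    rng = np.random.default_rng(seed)

    sequences: list[SequenceRecord] = []
    fam_lab: dict[str, str] = {}
    super_lab: dict[str, str] = {}
    annotations = AnnotationTable()
    fam_members: dict[str, list[str]] = {}
    for i in range(n_super):
        length = int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
        ancestor = "".join(AA20[j] for j in rng.integers(len(AA20), size=length))
        for j in range(fam_per_super):
            center = _mutate(ancestor, mut_rate_between, rng)
            fam_id = f"super{i:02d}_fam{j:02d}"
            genera = list(rng.choice(GENUS_POOL, size=int(rng.integers(1, 4)), replace=False))
            members: list[str] = []
            for k in range(members_per_fam):
                sid = f"s{i:02d}f{j:02d}m{k:03d}"
                sequences.append(SequenceRecord(
                    id=sid, description=fam_id,
                    residues=_mutate(center, mut_rate_within, rng)))
                fam_lab[sid] = fam_id
                super_lab[sid] = f"super{i:02d}"
                annotations.rows[sid] = {
                    "function": f"function_{fam_id}",
                    "taxon_genus": str(genera[rng.integers(len(genera))]),
                }
                members.append(sid)
            fam_members[fam_id] = members

    edges: list[HomologyEdge] = []
    fams_by_super: dict[str, list[str]] = {}
    for fam_id in fam_members:
        fams_by_super.setdefault(fam_id.split("_")[0], []).append(fam_id)
    for fam_id, members in fam_members.items():
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                edges.append(HomologyEdge(members[a_idx], members[b_idx],
                                          _band_draw(wmu, wsd, rng), 1e-50))
    for fams in fams_by_super.values():
        for fi in range(len(fams)):
            for fj in range(fi + 1, len(fams)):
                ma, mb = fam_members[fams[fi]], fam_members[fams[fj]]
                n_cross = max(1, int(cross_family_fraction * len(ma) * len(mb)))
                for _ in range(n_cross):
                    a = ma[rng.integers(len(ma))]
                    b = mb[rng.integers(len(mb))]
                    edges.append(HomologyEdge(a, b, _band_draw(bmu, bsd, rng), 1e-20))

    ids = [r.id for r in sequences]
    vectors, vsuper, vfam = synth_embeddings(
        n_super=n_super, fam_per_super=fam_per_super, members_per_fam=members_per_fam,
        d=embed_dim, sep_super=sep_super, sep_fam=sep_fam, noise_sd=noise_sd,
        seed=seed, ids=ids,
    )
    return PlantedWorld(
        sequences=sequences,
        superfamily_partition=Partition("truth:superfamily", super_lab),
        family_partition=Partition("truth:family", fam_lab),
        edges=edges,
        vectors=vectors,
        annotations=annotations,
        seed=seed,
        params={
            "n_super": n_super, "fam_per_super": fam_per_super,
            "members_per_fam": members_per_fam, "seq_len_range": seq_len_range,
            "mut_rate_within": mut_rate_within, "mut_rate_between": mut_rate_between,
            "within_band": within_band, "between_band": between_band,
            "cross_family_fraction": cross_family_fraction,
        },
    )


def make_edge_bands(
    partition: Partition,
    within_mu: float = 250.0,
    within_sd: float = 10.0,
    between_mu: float = 120.0,
    between_sd: float = 10.0,
    seed: int = 0,
    between_fraction: float = 0.05,
) -> list[HomologyEdge]:
    """Complete within-cluster edges plus sparse between-cluster edges.

    Scores are truncated normals from the two bands (clipped at 3 sd and at
    zero); inseparable bands raise :class:`ParameterError`, so any threshold
    between the bands recovers the partition exactly.
    """
    if within_mu - 3 * within_sd <= between_mu + 3 * between_sd:
        raise ParameterError("bands are not separable at 3 standard deviations")
    rng = np.random.default_rng(seed)
    clusters = {cid: sorted(m) for cid, m in partition.clusters().items()}
    edges: list[HomologyEdge] = []
    for members in clusters.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.append(HomologyEdge(members[i], members[j],
                                          _band_draw(within_mu, within_sd, rng), 1e-50))
    cids = sorted(clusters)
    for ci in range(len(cids)):
        for cj in range(ci + 1, len(cids)):
            ma, mb = clusters[cids[ci]], clusters[cids[cj]]
            n_cross = int(round(between_fraction * len(ma) * len(mb)))
            for _ in range(n_cross):
                a = ma[rng.integers(len(ma))]
                b = mb[rng.integers(len(mb))]
                edges.append(HomologyEdge(a, b, _band_draw(between_mu, between_sd, rng), 1e-20))
    return edges
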