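"""Fixed-length sequence vectors: pooling, PCA reduction, and synthetic fixtures.

Protein language models emit one vector per residue (e.g. 1280-d hidden
states); mean-pooling over the sequence dimension yields one fixed-length
vector per sequence, which is then reduced to a small number of dimensions
(30 by default) with PCA before clustering.  The model itself sits behind a
simple adapter (id -> per-residue matrix, or a file of precomputed pooled
vectors), so no GPU or model weights are ever required here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .components import Partition
from .errors import DimensionError, EmptyInputError

DEFAULT_REDUCED_DIMS = 30


@dataclass
class EmbeddingMatrix:
    """Id-aligned fixed-dimension vectors with provenance."""

    ids: list[str]
    X: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise DimensionError(
                f"matrix shape {self.X.shape} does not match {len(self.ids)} ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("embedding ids must be unique")
        if not np.isfinite(self.X).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {sid: i for i, sid in enumerate(self.ids)}
        return np.array([lookup[sid] for sid in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        idx = self.index_of(ids)
        return EmbeddingMatrix(list(ids), self.X[idx], dict(self.provenance))

    def save(self, path: str | Path) -> None:
        """Portable binary table (float32 matrix + id list) with a JSON sidecar."""
        path = Path(path)
        np.savez(path, ids=np.array(self.ids), X=self.X.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json") if path.suffix else Path(str(path) + ".json")
        sidecar.write_text(json.dumps(self.provenance, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingMatrix":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        data = np.load(path, allow_pickle=False)
        sidecar = Path(str(path).removesuffix(".npz") + ".json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(list(map(str, data["ids"])), np.asarray(data["X"], dtype=float), prov)


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Average per-residue states over the sequence dimension (L x d -> d)."""
    per_residue = np.asarray(per_residue, dtype=float)
    if per_residue.ndim != 2 or per_residue.shape[0] == 0:
        raise EmptyInputError("per-residue matrix must be non-empty and 2-D")
    return per_residue.mean(axis=0)


@dataclass
class ReductionModel:
    """Fitted PCA: centering mean, orthonormal components, variance fractions."""

    mean: np.ndarray                 # (d_in,)
    components: np.ndarray           # (d_out, d_in), rows orthonormal
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def fit_reduce(emb: EmbeddingMatrix, d_out: int = DEFAULT_REDUCED_DIMS) -> tuple[ReductionModel, EmbeddingMatrix]:
    """Center and project onto the top ``d_out`` principal components.

    Deterministic sign convention: within each component the loading of
    largest magnitude is made positive.  Requires more samples than output
    dimensions.
    """
    if d_out >= emb.n:
        raise DimensionError(f"d_out={d_out} must be < n_sequences={emb.n}")
    d_out = min(d_out, emb.d)
    mean = emb.X.mean(axis=0)
    centered = emb.X - mean
    # thin SVD; components are right singular vectors
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:d_out]
    # fix signs for reproducibility
    flip = np.sign(components[np.arange(d_out), np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    var = s**2 / max(emb.n - 1, 1)
    ratio = var[:d_out] / var.sum() if var.sum() > 0 else np.zeros(d_out)
    model = ReductionModel(mean=mean, components=components, explained_variance_ratio=ratio)
    prov = dict(emb.provenance)
    prov.update({"reduced": True, "d": d_out})
    return model, EmbeddingMatrix(list(emb.ids), centered @ components.T, prov)


def synth_embeddings(
    n_super: int = 8,
    fam_per_super: int = 4,
    members_per_fam: int = 25,
    d: int = 30,
    sep_super: float = 100.0,
    sep_fam: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> tuple[EmbeddingMatrix, Partition, Partition]:
    """Two-level hierarchical Gaussian-mixture vectors with planted labels.

    Emulates superfamily -> family organization: superfamily means are drawn
    so their expected pairwise distance is ~``sep_super``, family means sit
    around their superfamily mean at expected pairwise distance ~``sep_fam``,
    and members add isotropic noise whose expected member-member distance is
    ~``noise_sd``.  All three scales are therefore directly comparable, and
    ``sep_fam / noise_sd`` is the family separation-to-noise ratio.

    Returns the matrix plus ground-truth partitions at the superfamily and
    family levels.  Fully deterministic under ``seed``.
    """
    if sep_super <= 0 or sep_fam <= 0:
        raise ValueError("separations must be positive")
    rng = np.random.default_rng(seed)
    # pairwise distance between two N(0, s^2 I_d) points has mean ~ s*sqrt(2d)
    scale = np.sqrt(2 * d)
    super_means = rng.normal(0.0, sep_super / scale, size=(n_super, d))
    n = n_super * fam_per_super * members_per_fam
    X = np.empty((n, d))
    gen_ids: list[str] = []
    super_lab: dict[str, str] = {}
    fam_lab: dict[str, str] = {}
    row = 0
    for i in range(n_super):
        for j in range(fam_per_super):
            fam_mean = super_means[i] + rng.normal(0.0, sep_fam / scale, size=d)
            for k in range(members_per_fam):
                X[row] = fam_mean + rng.normal(0.0, noise_sd / scale, size=d)
                sid = f"s{i:02d}_f{j:02d}_m{k:03d}"
                gen_ids.append(sid)
                row += 1
    if ids is not None:
        if len(ids) != n:
            raise DimensionError(f"need exactly {n} ids, got {len(ids)}")
        gen_ids = list(ids)
    row = 0
    for i in range(n_super):
        for j in range(fam_per_super):
            for k in range(members_per_fam):
                sid = gen_ids[row]
                super_lab[sid] = f"super{i:02d}"
                fam_lab[sid] = f"super{i:02d}_fam{j:02d}"
                row += 1
    emb = EmbeddingMatrix(
        gen_ids, X,
        provenance={"source": "synthetic", "pooling": "mean", "reduced": False, "d": d,
                    "seed": seed, "sep_super": sep_super, "sep_fam": sep_fam,
                    "noise_sd": noise_sd},
    )
    return (
        emb,
        Partition(level="truth:superfamily", assignment=super_lab),
        Partition(level="truth:family", assignment=fam_lab),
    )
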