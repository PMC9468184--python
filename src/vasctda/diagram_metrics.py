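"""Sliced Wasserstein comparison of persistence diagrams, and classical MDS.

The Sliced Wasserstein (SW) distance between two diagrams ``Dg1`` and ``Dg2``
averages, over line directions ``θ ∈ (−π/2, π/2]``, the 1-Wasserstein distance
between the projections of the two diagrams onto the line — after augmenting
each diagram with the orthogonal projection of the *other* diagram onto the
diagonal ``y = x``, which equalises the masses and makes the line-Wasserstein
distance an exact sorted-difference sum:

    SW(Dg1, Dg2) = (1/π) ∫ W1(μ1_θ + μ2Δ_θ, μ2_θ + μ1Δ_θ) dθ

The integral is discretised with ``n_slices`` midpoint angles.  The similarity
kernel is ``k_SW = exp(−SW / (2σ²))`` — the exponent uses SW itself, not SW²;
this is the printed definition this package follows (the literature varies).

Diagrams are compared per homology dimension and the per-dimension distances
combined (default: sum over dims 1 and 2, loops and voids).  Sets of diagrams
are embedded in the plane with classical (Torgerson) MDS on the SW distance
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rips import PersistenceDiagram

__all__ = [
    "SWConfig",
    "DistanceMatrix",
    "sw_distance",
    "sw_kernel",
    "pairwise_distance_matrix",
    "mds_embed",
    "mds_strain",
]


@dataclass(frozen=True)
class SWConfig:
    """Settings for Sliced Wasserstein comparisons.

    ``n_slices``: number of projection angles discretising (−π/2, π/2];
    ``sigma``: kernel scale σ (same units as the diagrams, μm);
    ``dims``: homology dimensions entering the comparison;
    ``aggregation``: how per-dimension distances combine (only ``"sum"``).
    """

    n_slices: int = 50
    sigma: float = 1.0
    dims: tuple[int, ...] = (1, 2)
    aggregation: str = "sum"

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.aggregation != "sum":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, plus labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix size must match the label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def _diagram_points(dg, dim: int | None) -> np.ndarray:
    """(n, 2) finite (birth, death) points; raises on capped/infinite pairs."""
    if isinstance(dg, PersistenceDiagram):
        if dim is None:
            raise ValueError("dim required when passing a PersistenceDiagram")
        if any(p.capped for p in dg.in_dim(dim)):
            raise ValueError(
                f"diagram has capped/infinite pairs in dim {dim}; filter them first"
            )
        return dg.array(dim, finite_only=True)
    arr = np.asarray(dg, dtype=float)
    if arr.size == 0:
        return np.empty((0, 2))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (birth, death)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("diagram points must be finite")
    return arr


def _sw_points(a: np.ndarray, b: np.ndarray, n_slices: int) -> float:
    """SW distance between two finite (n, 2) diagrams."""
    if len(a) == 0 and len(b) == 0:
        return 0.0
    theta = -np.pi / 2 + np.pi * (np.arange(n_slices) + 0.5) / n_slices
    w = np.stack([np.cos(theta), np.sin(theta)])  # (2, M)

    def diag_proj(p: np.ndarray) -> np.ndarray:
        m = (p[:, 0] + p[:, 1]) / 2.0
        return np.column_stack([m, m])

    side1 = np.vstack([a, diag_proj(b)]) if len(b) else a
    side2 = np.vstack([b, diag_proj(a)]) if len(a) else b
    p1 = side1 @ w  # (n, M)
    p2 = side2 @ w
    p1.sort(axis=0)
    p2.sort(axis=0)
    return float(np.mean(np.sum(np.abs(p1 - p2), axis=0)))


def sw_distance(dg1, dg2, cfg: SWConfig | None = None, dim: int | None = None) -> float:
    """Sliced Wasserstein distance between two diagrams.

    With :class:`PersistenceDiagram` inputs the per-dimension distances over
    ``cfg.dims`` are combined according to ``cfg.aggregation`` (pass ``dim``
    to restrict to a single dimension).  Raw ``(n, 2)`` arrays are compared
    directly.  ``SW(∅, ∅) = 0`` by convention.
    """
    cfg = cfg or SWConfig()
    if isinstance(dg1, PersistenceDiagram) or isinstance(dg2, PersistenceDiagram):
        dims = (dim,) if dim is not None else cfg.dims
        return float(
            sum(
                _sw_points(_diagram_points(dg1, d), _diagram_points(dg2, d), cfg.n_slices)
                for d in dims
            )
        )
    return _sw_points(_diagram_points(dg1, None if dim is None else dim),
                      _diagram_points(dg2, None if dim is None else dim),
                      cfg.n_slices)


def sw_kernel(dg1, dg2, cfg: SWConfig | None = None, dim: int | None = None) -> float:
    """Similarity kernel ``exp(−SW / (2σ²))`` in (0, 1]."""
    cfg = cfg or SWConfig()
    return float(np.exp(-sw_distance(dg1, dg2, cfg, dim) / (2.0 * cfg.sigma**2)))


def pairwise_distance_matrix(diagrams, cfg: SWConfig | None = None,
                             labels=None, drop_capped: bool = True) -> DistanceMatrix:
    """All-pairs SW distance matrix over a list of diagrams.

    Capped (still-alive) pairs are excluded from the comparison by default.
    """
    cfg = cfg or SWConfig()
    diagrams = list(diagrams)
    if len(diagrams) < 2:
        raise ValueError("need at least 2 diagrams")
    if labels is None:
        labels = [
            (dg.meta.get("label") if isinstance(dg, PersistenceDiagram) else None) or str(i)
            for i, dg in enumerate(diagrams)
        ]
    labels = [str(l) for l in labels]
    per_dim: list[list[np.ndarray]] = []
    for dg in diagrams:
        if isinstance(dg, PersistenceDiagram):
            per_dim.append([dg.array(d, finite_only=drop_capped) for d in cfg.dims])
        else:
            raise TypeError("pairwise_distance_matrix expects PersistenceDiagram objects")
    k = len(diagrams)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = sum(
                _sw_points(per_dim[i][m], per_dim[j][m], cfg.n_slices)
                for m in range(len(cfg.dims))
            )
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out)


def mds_embed(dm: DistanceMatrix | np.ndarray, out_dim: int = 2):
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centres the squared distances, takes the top ``out_dim``
    eigenpairs, and scales eigenvectors by the square roots of the (clipped)
    eigenvalues.  Deterministic up to rigid motion and reflection; a fixed
    sign convention (largest-magnitude entry positive per axis) makes repeated
    runs bit-identical.

    Returns ``(coords, eigenvalues)``: coords is (k, out_dim), eigenvalues the
    full descending spectrum of the centred Gram matrix (negative values
    diagnose non-Euclidean distances).
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.values
    else:
        d = np.asarray(dm, dtype=float)
    k = d.shape[0]
    if out_dim >= k:
        raise ValueError("out_dim must be smaller than the number of objects")
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = np.clip(eigval[:out_dim], 0.0, None)
    coords = eigvec[:, :out_dim] * np.sqrt(lam)
    for c in range(out_dim):
        col = coords[:, c]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords, eigval


def mds_strain(d_in: np.ndarray, coords: np.ndarray) -> float:
    """Relative squared mismatch between input and embedded distances."""
    d_in = d_in.values if isinstance(d_in, DistanceMatrix) else np.asarray(d_in, float)
    diff = coords[:, None, :] - coords[None, :, :]
    d_emb = np.sqrt((diff**2).sum(axis=2))
    denom = (d_in**2).sum()
    if denom == 0:
        return float((d_emb**2).sum())
    return float(((d_emb - d_in) ** 2).sum() / denom)
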