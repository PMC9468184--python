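"""Vietoris–Rips persistent homology of 3D point clouds.

The filtration parameter is the **ball radius** r: every point grows a ball of
radius r, and a simplex enters the complex once all its pairwise balls
intersect, i.e. once every pairwise distance is ≤ 2r.  Births and deaths are
therefore half the corresponding simplex diameters.  (Most PH engines report
the edge-length/diameter scale; everything here is already divided by 2.)

H0 comes from the minimum spanning tree of the distance matrix (the Rips
single-linkage dendrogram).  H1 and H2 are computed over Z/2 with the dual
(persistent cohomology) reduction: for each dimension, coboundary columns are
processed in decreasing filtration order, and a column's pivot is its
earliest cofacet.  Almost every column claims its initial pivot without any
arithmetic, which is what makes Rips computations tractable; columns paired
as pivots one dimension down are cleared from the next pass.  Cofacets are
enumerated on the fly from the distance matrix, so simplices one dimension
above the requested maximum are never materialised globally.

Zero-persistence pairs (death == birth, ubiquitous in Rips complexes) are
dropped.  Features still alive at ``max_radius`` are recorded with
``death = max_radius`` and ``capped=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .volume_io import PointCloud3D

__all__ = [
    "PersistencePair",
    "PersistenceDiagram",
    "rips_persistence",
    "filter_diagram",
    "read_diagram",
    "write_diagram",
]


@dataclass(frozen=True)
class PersistencePair:
    """One topological feature: ``dim`` ∈ {0, 1, 2}, birth/death radii in μm."""

    dim: int
    birth: float
    death: float
    capped: bool = False

    def __post_init__(self):
        if self.dim not in (0, 1, 2):
            raise ValueError(f"dim must be 0, 1 or 2, got {self.dim}")
        if not (0 <= self.birth <= self.death):
            raise ValueError(f"need 0 <= birth <= death, got ({self.birth}, {self.death})")

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Multiset of persistence pairs plus provenance metadata."""

    pairs: list[PersistencePair]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = sorted(self.pairs, key=lambda p: (p.dim, p.birth, p.death))

    def __len__(self) -> int:
        return len(self.pairs)

    def in_dim(self, dim: int, finite_only: bool = False) -> list[PersistencePair]:
        return [p for p in self.pairs if p.dim == dim and not (finite_only and p.capped)]

    def array(self, dim: int, finite_only: bool = True) -> np.ndarray:
        """(n, 2) array of (birth, death) for one dimension."""
        sel = self.in_dim(dim, finite_only=finite_only)
        if not sel:
            return np.empty((0, 2))
        return np.array([[p.birth, p.death] for p in sel])


# ---------------------------------------------------------------------------
# simplex enumeration (up to triangles; tetrahedra only appear as cofacets)
# ---------------------------------------------------------------------------

def _enumerate_edges(dist: np.ndarray, thr: float):
    n = dist.shape[0]
    i, j = np.triu_indices(n, k=1)
    d = dist[i, j]
    keep = d <= thr
    return np.column_stack([i[keep], j[keep]]).astype(np.int32), d[keep]


def _triangles_from_edges(edges: np.ndarray, diam: np.ndarray, dist: np.ndarray, thr: float):
    """All triangles (i<j<k) with diameter <= thr, built by extending edges."""
    n = dist.shape[0]
    last = edges[:, 1]
    counts = n - 1 - last
    if counts.sum() == 0:
        return np.empty((0, 3), dtype=np.int32), np.empty(0)
    parent = np.repeat(np.arange(len(edges)), counts)
    new_v = np.concatenate([np.arange(l + 1, n) for l in last]).astype(np.int32)
    out = np.column_stack([edges[parent], new_v])
    d = np.maximum(diam[parent], dist[out[:, 0], new_v])
    d = np.maximum(d, dist[out[:, 1], new_v])
    keep = d <= thr
    return out[keep], d[keep]


def _sort_filtration(simp: np.ndarray, diam: np.ndarray):
    """Order simplices by (diameter, lexicographic vertices)."""
    keys = tuple(simp[:, c] for c in reversed(range(simp.shape[1]))) + (diam,)
    order = np.lexsort(keys)
    return simp[order], diam[order]


# ---------------------------------------------------------------------------
# cohomology reduction
# ---------------------------------------------------------------------------

def _initial_copivots(simp: np.ndarray, diam: np.ndarray, dist: np.ndarray, thr: float):
    """Earliest cofacet of each simplex: (diameter, added vertex).

    Among equal-diameter cofacets the filtration tiebreak is lexicographic on
    the sorted vertex tuple, which for cofacets of a fixed simplex is
    equivalent to ordering by the added vertex.
    """
    m, k = simp.shape
    n = dist.shape[0]
    dmin = np.full(m, np.inf)
    vmin = np.full(m, -1, dtype=np.int64)
    if m == 0:
        return dmin, vmin
    chunk = max(1, int(1e7) // n)
    cols = np.arange(n)
    for s in range(0, m, chunk):
        e = min(m, s + chunk)
        sub = simp[s:e]
        d = dist[sub[:, 0]].copy()
        for c in range(1, k):
            np.maximum(d, dist[sub[:, c]], out=d)
        np.maximum(d, diam[s:e, None], out=d)
        rows = np.arange(e - s)[:, None]
        d[rows, sub] = np.inf
        d[d > thr] = np.inf
        dm = d.min(axis=1)
        finite = np.isfinite(dm)
        tie = d == dm[:, None]
        vm = np.where(tie, cols[None, :], n + 1).min(axis=1)
        dmin[s:e] = dm
        vmin[s:e] = np.where(finite, vm, -1)
    return dmin, vmin


def _cofacet_column(verts, sdiam: float, dist: np.ndarray, thr: float) -> set:
    """Full coboundary of one simplex as a set of keys (diam, v0, ..., vk)."""
    d = dist[verts[0]].copy()
    for u in verts[1:]:
        np.maximum(d, dist[u], out=d)
    np.maximum(d, sdiam, out=d)
    d[list(verts)] = np.inf
    out = set()
    for v in np.nonzero(d <= thr)[0]:
        out.add((float(d[v]), *sorted((*[int(u) for u in verts], int(v)))))
    return out


def _cohomology_pass(simp: np.ndarray, diam: np.ndarray, dist: np.ndarray, thr: float,
                     n: int, columns: np.ndarray, cleared: set[int] | None = None):
    """One dual-reduction pass over the selected columns.

    ``columns`` is a boolean mask over ``simp`` rows (already in ascending
    filtration order); processing runs in descending order.  ``cleared``
    holds vertex codes of simplices paired as pivots one dimension down.

    Returns ``(pairs, claimed_codes, essential_rows)``: ``pairs`` as
    (birth-diam, death-diam) with positive persistence, ``claimed_codes`` the
    packed vertex codes of the cofacets used as pivots (cleared in the next
    dimension), ``essential_rows`` the row indices of columns that reduced to
    zero (classes alive at the threshold).
    """
    dmin, vmin = _initial_copivots(simp, diam, dist, thr)
    base = np.int64(n)
    k = simp.shape[1]
    # packed code of each column simplex, to test clearing
    code_self = np.zeros(len(simp), dtype=np.int64)
    for c in range(k):
        code_self = code_self * base + simp[:, c]

    claimed: dict[int, int] = {}
    reduced: dict[int, set] = {}
    pairs: list[tuple[float, float]] = []
    essential: list[int] = []

    def pack(verts) -> int:
        code = 0
        for u in verts:
            code = code * int(base) + int(u)
        return code

    def cofacet_code(row: int) -> int:
        verts = sorted((*[int(u) for u in simp[row]], int(vmin[row])))
        return pack(verts)

    for row in range(len(simp) - 1, -1, -1):
        if not columns[row]:
            continue
        if cleared is not None and int(code_self[row]) in cleared:
            continue
        if vmin[row] < 0:
            essential.append(row)
            continue
        piv = cofacet_code(row)
        if piv not in claimed:
            claimed[piv] = row
            if dmin[row] > diam[row]:
                pairs.append((float(diam[row]), float(dmin[row])))
            continue
        # rare path: genuine reduction against previously claimed columns
        col = _cofacet_column(simp[row], float(diam[row]), dist, thr)
        while col:
            key = min(col)
            code = pack(key[1:])
            owner = claimed.get(code)
            if owner is None:
                claimed[code] = row
                reduced[row] = col
                if key[0] > diam[row]:
                    pairs.append((float(diam[row]), float(key[0])))
                break
            ocol = reduced.get(owner)
            if ocol is None:
                ocol = _cofacet_column(simp[owner], float(diam[owner]), dist, thr)
            col = col ^ ocol
        else:
            essential.append(row)
    return pairs, set(claimed), essential


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def rips_persistence(cloud, max_dim: int = 2, max_radius: float | None = None) -> PersistenceDiagram:
    """Persistence diagram of the Vietoris–Rips filtration of a point cloud.

    Parameters
    ----------
    cloud : PointCloud3D or (N, d) array
        Input points (μm).
    max_dim : int
        Highest homology dimension, 0–2.  Cost grows steeply with N for
        ``max_dim=2``; subsample first (:func:`vasctda.volume_io.subsample`)
        on large clouds.
    max_radius : float, optional
        Filtration cutoff (ball radius, μm).  Defaults to half the
        bounding-box diagonal, which closes every finite feature of clouds
        whose diameter does not exceed the box diagonal.
    """
    coords = cloud.coords if isinstance(cloud, PointCloud3D) else np.atleast_2d(np.asarray(cloud, dtype=float))
    n = len(coords)
    if n == 0:
        raise ValueError("cannot compute persistence of an empty cloud")
    if max_dim not in (0, 1, 2):
        raise ValueError("max_dim must be 0, 1 or 2")
    if max_radius is None:
        if n == 1:
            max_radius = 1.0
        else:
            span = coords.max(axis=0) - coords.min(axis=0)
            max_radius = float(np.linalg.norm(span)) / 2.0
            if max_radius == 0.0:
                max_radius = 1.0
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    thr = 2.0 * max_radius  # simplex-diameter scale

    pairs: list[PersistencePair] = []
    meta = {"n_points": n, "max_dim": max_dim, "max_radius": float(max_radius)}
    if isinstance(cloud, PointCloud3D):
        meta["channel"] = cloud.channel

    dist = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))

    # --- H0 from the minimum spanning tree (single linkage) ----------------
    if n > 1:
        # shift all edge weights by +1 so duplicate points (distance 0) are
        # not silently dropped by the sparse MST; a uniform shift preserves
        # the tree
        shifted = dist + 1.0
        np.fill_diagonal(shifted, 0.0)
        mst = minimum_spanning_tree(shifted).tocoo()
        w = np.sort(mst.data) - 1.0
        merged = w[w <= thr]
        for d in merged:
            if d > 0:
                pairs.append(PersistencePair(0, 0.0, float(d) / 2.0))
        n_components = n - len(merged)
    else:
        n_components = 1
    for _ in range(n_components):
        pairs.append(PersistencePair(0, 0.0, float(max_radius), capped=True))

    if max_dim >= 1 and n >= 3:
        edges, ed = _enumerate_edges(dist, thr)
        edges, ed = _sort_filtration(edges, ed)

        # edges merging two components are deaths in dim 0: cleared here
        creators = np.zeros(len(edges), dtype=bool)
        creators[_cycle_creating_edges(n, edges)] = True

        pairs1, claimed_tri, essential1 = _cohomology_pass(
            edges, ed, dist, thr, n, columns=creators
        )
        pairs.extend(PersistencePair(1, b / 2.0, d / 2.0) for b, d in pairs1)
        for row in essential1:
            pairs.append(PersistencePair(1, float(ed[row]) / 2.0, float(max_radius), capped=True))

        if max_dim >= 2 and n >= 4:
            tri, td = _triangles_from_edges(edges, ed, dist, thr)
            tri, td = _sort_filtration(tri, td)
            pairs2, _, essential2 = _cohomology_pass(
                tri, td, dist, thr, n,
                columns=np.ones(len(tri), dtype=bool), cleared=claimed_tri,
            )
            pairs.extend(PersistencePair(2, b / 2.0, d / 2.0) for b, d in pairs2)
            for row in essential2:
                pairs.append(PersistencePair(2, float(td[row]) / 2.0, float(max_radius), capped=True))

    return PersistenceDiagram(pairs, meta)


def _cycle_creating_edges(n: int, edges: np.ndarray) -> list[int]:
    """Indices (in filtration order) of edges joining already-connected parts."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    creators = []
    for r, (i, j) in enumerate(edges):
        ri, rj = find(int(i)), find(int(j))
        if ri == rj:
            creators.append(r)
        else:
            parent[ri] = rj
    return creators


# ---------------------------------------------------------------------------
# diagram post-processing and serialization
# ---------------------------------------------------------------------------

def filter_diagram(pd_: PersistenceDiagram, dim: int, min_persistence: float = 0.0) -> PersistenceDiagram:
    """Keep pairs of one dimension with lifetime ``death - birth >= min_persistence``."""
    if min_persistence < 0:
        raise ValueError("min_persistence must be >= 0")
    kept = [p for p in pd_.pairs if p.dim == dim and p.persistence >= min_persistence]
    meta = dict(pd_.meta)
    meta["filtered_dim"] = dim
    meta["min_persistence"] = min_persistence
    return PersistenceDiagram(kept, meta)


def write_diagram(pd_: PersistenceDiagram, path) -> None:
    """CSV serialization with columns ``dim,birth_um,death_um,capped``."""
    df = pd.DataFrame(
        {
            "dim": [p.dim for p in pd_.pairs],
            "birth_um": [p.birth for p in pd_.pairs],
            "death_um": [p.death for p in pd_.pairs],
            "capped": [int(p.capped) for p in pd_.pairs],
        }
    )
    df.to_csv(path, index=False)


def read_diagram(path) -> PersistenceDiagram:
    df = pd.read_csv(path)
    for col in ("dim", "birth_um", "death_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    pairs = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        birth, death = float(row.birth_um), float(row.death_um)
        capped = bool(getattr(row, "capped", 0)) or math.isinf(death)
        if death < birth or birth < 0:
            raise ValueError(f"{path}: line {line}: invalid pair ({birth}, {death})")
        pairs.append(PersistencePair(int(row.dim), birth, death, capped))
    return PersistenceDiagram(pairs, {"source": str(path)})
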