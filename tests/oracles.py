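"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and kept separate from the package:
persistent homology via persistent-Betti ranks over Z/2 (no column reduction,
no pairing algorithm), the Sliced Wasserstein distance via adaptive
quadrature, Fisher's exact test via full hypergeometric enumeration, and
nearest neighbours by exhaustive search.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy import integrate
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# GF(2) linear algebra
# ---------------------------------------------------------------------------

def gf2_rref(mat: np.ndarray):
    """Reduced row echelon form over Z/2; returns (rref, pivot column list)."""
    m = mat.astype(np.uint8).copy()
    rows, cols = m.shape
    pivots = []
    r = 0
    for c in range(cols):
        if r >= rows:
            break
        hit = np.nonzero(m[r:, c])[0]
        if len(hit) == 0:
            continue
        pr = r + hit[0]
        m[[r, pr]] = m[[pr, r]]
        others = np.nonzero(m[:, c])[0]
        for o in others:
            if o != r:
                m[o] ^= m[r]
        pivots.append(c)
        r += 1
    return m, pivots


def gf2_rank(mat: np.ndarray) -> int:
    if mat.size == 0:
        return 0
    _, pivots = gf2_rref(mat)
    return len(pivots)


def gf2_nullspace(mat: np.ndarray) -> np.ndarray:
    """Basis (columns) of the null space of ``mat`` over Z/2."""
    rows, cols = mat.shape
    if cols == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    if rows == 0:
        return np.eye(cols, dtype=np.uint8)
    rref, pivots = gf2_rref(mat)
    free = [c for c in range(cols) if c not in pivots]
    basis = np.zeros((cols, len(free)), dtype=np.uint8)
    for k, fc in enumerate(free):
        basis[fc, k] = 1
        for r, pc in enumerate(pivots):
            if rref[r, fc]:
                basis[pc, k] = 1
    return basis


# ---------------------------------------------------------------------------
# brute-force persistent homology
# ---------------------------------------------------------------------------

def _all_simplices(n: int, dist: np.ndarray, top_dim: int, thr: float):
    """Per dimension: list of (vertex-tuple, diameter) with diameter <= thr."""
    by_dim: dict[int, list[tuple[tuple, float]]] = {0: [((v,), 0.0) for v in range(n)]}
    for d in range(1, top_dim + 1):
        entries = []
        for verts in itertools.combinations(range(n), d + 1):
            diam = max(dist[a][b] for a, b in itertools.combinations(verts, 2))
            if diam <= thr:
                entries.append((verts, diam))
        by_dim[d] = entries
    return by_dim


def rips_diagram_bruteforce(coords, max_dim: int, max_radius: float | None = None):
    """Rips persistence via persistent-Betti numbers β_d(i, j) from Z/2 ranks.

    Returns ``{dim: [(birth, death), ...]}`` on the ball-radius scale, with
    ``death = inf`` for features still alive at the threshold.  Pair
    multiplicities come from the inclusion-exclusion formula on persistent
    Betti numbers, which never references the reduction algorithm under test.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    dist = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    if max_radius is None:
        max_radius = dist.max() / 2.0 if n > 1 else 1.0
        if max_radius == 0:
            max_radius = 1.0
    thr = 2.0 * max_radius
    top = max_dim + 1
    simplices = _all_simplices(n, dist, top, thr)

    values = sorted({0.0} | {diam for d in range(1, top + 1) for _, diam in simplices[d]})
    m = len(values)

    # index simplices once per dimension; columns of boundary matrices follow
    index = {d: {verts: k for k, (verts, _) in enumerate(simplices[d])} for d in simplices}
    diams = {d: np.array([diam for _, diam in simplices[d]]) for d in simplices}

    boundary = {}
    for d in range(1, top + 1):
        mat = np.zeros((len(simplices[d - 1]), len(simplices[d])), dtype=np.uint8)
        for col, (verts, _) in enumerate(simplices[d]):
            for drop in range(len(verts)):
                face = verts[:drop] + verts[drop + 1 :]
                mat[index[d - 1][face], col] = 1
        boundary[d] = mat

    def counts_at(d: int, vi: int) -> np.ndarray:
        return diams[d] <= values[vi] + 1e-12

    def betti_pers(d: int, vi: int, vj: int) -> int:
        """β_d(K_i → K_j) = dim Z_d(K_i) − dim(B_d(K_j) ∩ Z_d(K_i))."""
        pres_i = counts_at(d, vi)
        if d == 0:
            z_basis = np.eye(n, dtype=np.uint8)  # every vertex chain is a cycle
            z_cols = z_basis
        else:
            sub = boundary[d][:, pres_i]
            null = gf2_nullspace(sub)
            z_cols = np.zeros((len(simplices[d]), null.shape[1]), dtype=np.uint8)
            z_cols[np.nonzero(pres_i)[0][:, None], np.arange(null.shape[1])[None, :]] = null
        dim_z = z_cols.shape[1]
        if d + 1 in boundary:
            pres_j = counts_at(d + 1, vj)
            b_cols = boundary[d + 1][:, pres_j]
        else:
            b_cols = np.zeros((len(simplices[d]), 0), dtype=np.uint8)
        dim_b = gf2_rank(b_cols)
        dim_sum = gf2_rank(np.concatenate([z_cols, b_cols], axis=1))
        dim_intersection = dim_z + dim_b - dim_sum
        return dim_z - dim_intersection

    out: dict[int, list[tuple[float, float]]] = {d: [] for d in range(max_dim + 1)}
    for d in range(max_dim + 1):
        beta = {}
        for vi in range(m):
            for vj in range(vi, m):
                beta[(vi, vj)] = betti_pers(d, vi, vj)

        def b(vi, vj):
            if vi < 0:
                return 0
            return beta[(vi, vj)]

        for vi in range(m):
            for vj in range(vi + 1, m):
                mult = (
                    b(vi, vj - 1) - b(vi, vj) - b(vi - 1, vj - 1) + b(vi - 1, vj)
                )
                for _ in range(mult):
                    out[d].append((values[vi] / 2.0, values[vj] / 2.0))
            mult_ess = b(vi, m - 1) - b(vi - 1, m - 1)
            for _ in range(mult_ess):
                out[d].append((values[vi] / 2.0, np.inf))
        out[d].sort()
    return out


# ---------------------------------------------------------------------------
# Sliced Wasserstein quadrature oracle
# ---------------------------------------------------------------------------

def sw_quadrature(dg1: np.ndarray, dg2: np.ndarray, tol: float = 1e-10) -> float:
    """SW distance by adaptive quadrature over the projection angle."""
    dg1 = np.atleast_2d(np.asarray(dg1, dtype=float)) if np.size(dg1) else np.empty((0, 2))
    dg2 = np.atleast_2d(np.asarray(dg2, dtype=float)) if np.size(dg2) else np.empty((0, 2))

    def diag(p):
        mid = (p[:, 0] + p[:, 1]) / 2.0
        return np.column_stack([mid, mid])

    side1 = np.vstack([dg1, diag(dg2)]) if len(dg2) else dg1
    side2 = np.vstack([dg2, diag(dg1)]) if len(dg1) else dg2
    if len(side1) == 0:
        return 0.0

    def w1(theta):
        w = np.array([np.cos(theta), np.sin(theta)])
        a = np.sort(side1 @ w)
        b = np.sort(side2 @ w)
        return np.abs(a - b).sum()

    val, _ = integrate.quad(w1, -np.pi / 2, np.pi / 2, limit=500, epsabs=tol, epsrel=tol)
    return val / np.pi


# ---------------------------------------------------------------------------
# Fisher's exact test by enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p: sum of hypergeometric probabilities <= that of the table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def weight(x: int) -> int:
        return comb(r1, x) * comb(r2, c1 - x)

    observed = weight(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum(weight(x) for x in range(lo, hi + 1) if weight(x) <= observed)
    return total / denom


# ---------------------------------------------------------------------------
# exhaustive nearest neighbours
# ---------------------------------------------------------------------------

def nn_bruteforce(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    src = np.atleast_2d(source)
    tgt = np.atleast_2d(target)
    out = np.empty(len(src))
    for i, p in enumerate(src):
        out[i] = np.sqrt(((tgt - p) ** 2).sum(axis=1)).min()
    return out
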