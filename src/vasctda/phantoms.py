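"""Seeded synthetic point-cloud phantoms with known topology and anisotropy.

These stand in for thresholded vessel voxel clouds so every analysis stage is
testable without imaging data: tubes (vessel segments), rings (ground-truth
loops, H1), shells (ground-truth voids, H2), bifurcating trees (branching
vasculature) and uniform clutter.  ``degrade_phantom`` emulates damaged or
fragmented vessels by deleting contiguous runs of points along the generation
order, which for tubes and trees corresponds to cutting out spatial segments.

All generators are deterministic per seed.  Point counts along centerlines
are Poisson with the requested linear density; transverse scatter and jitter
are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import PointCloud3D, VolumeStack

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "tube_phantom",
    "ring_phantom",
    "shell_phantom",
    "tree_phantom",
    "uniform_phantom",
    "degrade_phantom",
    "rasterize",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description (used by the CLI and pipelines)."""

    kind: str                      # tube | ring | shell | tree | uniform
    seed: int = 0
    radius: float = 100.0          # μm; tube radius, ring/shell radius, box edge
    length: float = 1000.0         # μm; tube length / tree root branch length
    density: float = 0.5           # points per μm of centerline (tube/tree/ring)
    n_points: int = 300            # shell / uniform point count
    depth: int = 3                 # tree bifurcation depth
    branch_angle: float = 40.0     # degrees
    jitter_sd: float = 0.0         # μm

    def __post_init__(self):
        if self.kind not in {"tube", "ring", "shell", "tree", "uniform"}:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.density <= 0 or self.radius <= 0 or self.length <= 0:
            raise ValueError("density, radius and length must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def make_phantom(spec: PhantomSpec) -> PointCloud3D:
    if spec.kind == "tube":
        return tube_phantom(spec.length, spec.radius, spec.density,
                            jitter_sd=spec.jitter_sd, seed=spec.seed)
    if spec.kind == "ring":
        return ring_phantom(spec.radius, density=spec.density,
                            jitter_sd=spec.jitter_sd, seed=spec.seed)
    if spec.kind == "shell":
        return shell_phantom(spec.radius, spec.n_points,
                             jitter_sd=spec.jitter_sd, seed=spec.seed)
    if spec.kind == "tree":
        return tree_phantom(spec.depth, spec.length, spec.radius, spec.density,
                            branch_angle=spec.branch_angle,
                            jitter_sd=spec.jitter_sd, seed=spec.seed)
    return uniform_phantom(spec.length, spec.n_points, seed=spec.seed)


def _scatter_tube(rng, start, direction, length, radius, density, jitter_sd):
    """Points scattered within a cylinder around a straight centerline,
    ordered along its axis."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = rng.poisson(density * length)
    t = np.sort(rng.uniform(0, length, size=n))
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    rad = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    pts = (
        np.asarray(start, dtype=float)
        + t[:, None] * direction
        + (rad * np.cos(phi))[:, None] * e1
        + (rad * np.sin(phi))[:, None] * e2
    )
    if jitter_sd > 0:
        pts = pts + rng.normal(scale=jitter_sd, size=pts.shape)
    return pts


def tube_phantom(length: float, radius: float, density: float,
                 jitter_sd: float = 0.0, seed: int = 0,
                 start=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)) -> PointCloud3D:
    """Straight vessel-segment surrogate: Poisson(density·length) points in a
    cylinder, ordered along the axis."""
    rng = np.random.default_rng(seed)
    pts = _scatter_tube(rng, start, direction, length, radius, density, jitter_sd)
    cloud = PointCloud3D(pts.reshape(-1, 3), channel="phantom_tube")
    cloud.meta.update({"seed": seed, "kind": "tube"})
    return cloud


def ring_phantom(radius: float, n_points: int | None = None, density: float | None = None,
                 jitter_sd: float = 0.0, seed: int = 0) -> PointCloud3D:
    """Points on a circle of radius R in the z=0 plane — a ground-truth loop.

    With ``n_points`` given, the points are equally spaced (deterministic
    geometry; the circle oracle for H1 applies exactly when jitter is 0);
    with ``density``, angles are uniform with Poisson count.
    """
    rng = np.random.default_rng(seed)
    if n_points is not None:
        phi = np.sort(2 * np.pi * np.arange(n_points) / n_points)
    elif density is not None:
        n = rng.poisson(density * 2 * np.pi * radius)
        phi = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    else:
        raise ValueError("give n_points or density")
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), np.zeros_like(phi)])
    if jitter_sd > 0:
        pts = pts + rng.normal(scale=jitter_sd, size=pts.shape)
    cloud = PointCloud3D(pts.reshape(-1, 3), channel="phantom_ring")
    cloud.meta.update({"seed": seed, "kind": "ring"})
    return cloud


def shell_phantom(radius: float, n_points: int, jitter_sd: float = 0.0,
                  seed: int = 0) -> PointCloud3D:
    """Points uniform on a sphere surface — a ground-truth void (H2)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_points, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = radius * v
    if jitter_sd > 0:
        pts = pts + rng.normal(scale=jitter_sd, size=pts.shape)
    cloud = PointCloud3D(pts.reshape(-1, 3), channel="phantom_shell")
    cloud.meta.update({"seed": seed, "kind": "shell"})
    return cloud


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def tree_phantom(depth: int, branch_length: float = 400.0, radius: float = 15.0,
                 density: float = 0.4, branch_angle: float = 40.0,
                 length_decay: float = 0.75, jitter_sd: float = 0.0,
                 seed: int = 0) -> PointCloud3D:
    """Recursive bifurcating tree of tubes: ``2^(depth+1) − 1`` segments.

    Each branch splits into two children rotated ±branch_angle about an
    alternating axis, with geometrically decaying lengths — a simple surrogate
    for branching vasculature.  Points are ordered segment by segment, so
    :func:`degrade_phantom` removes spatially contiguous pieces.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(branch_angle)
    segments: list[np.ndarray] = []
    n_segments = 0

    def grow(start, direction, length, level):
        nonlocal n_segments
        n_segments += 1
        pts = _scatter_tube(rng, start, direction, length, radius, density, jitter_sd)
        segments.append(pts)
        if level >= depth:
            return
        end = np.asarray(start) + length * np.asarray(direction)
        # alternate the bend plane with level so the tree fills 3D
        bend_axis = np.array([0.0, 1.0, 0.0]) if level % 2 == 0 else np.array([0.0, 0.0, 1.0])
        for sign in (+1.0, -1.0):
            rot = _rotation(bend_axis, sign * angle)
            child_dir = rot @ np.asarray(direction, dtype=float)
            grow(end, child_dir / np.linalg.norm(child_dir), length * length_decay, level + 1)

    grow(np.zeros(3), np.array([1.0, 0.0, 0.0]), branch_length, 0)
    pts = np.vstack([s for s in segments if len(s)]) if segments else np.empty((0, 3))
    cloud = PointCloud3D(pts.reshape(-1, 3), channel="phantom_tree")
    cloud.meta.update({"seed": seed, "kind": "tree", "n_segments": n_segments})
    return cloud


def uniform_phantom(box_edge: float, n_points: int, seed: int = 0) -> PointCloud3D:
    """Uniform clutter in a cube, for null comparisons."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, box_edge, size=(n_points, 3))
    cloud = PointCloud3D(pts, channel="phantom_uniform")
    cloud.meta.update({"seed": seed, "kind": "uniform"})
    return cloud


def degrade_phantom(cloud: PointCloud3D, drop_fraction: float,
                    clump_scale: int = 20, seed: int = 0) -> PointCloud3D:
    """Delete contiguous runs of points totalling ``drop_fraction`` of N.

    Runs are contiguous in point order (generation order follows the
    centerline for tubes/trees), so removal fragments the structure the way
    damaged vessels lose whole stretches rather than isolated voxels.
    ``clump_scale`` is the mean run length in points.
    """
    if not 0 <= drop_fraction <= 1:
        raise ValueError("drop_fraction must be in [0, 1]")
    if clump_scale < 1:
        raise ValueError("clump_scale must be >= 1")
    n = cloud.n
    target = int(round(drop_fraction * n))
    if target == 0:
        return cloud.select(np.ones(n, dtype=bool))
    rng = np.random.default_rng(seed)
    drop = np.zeros(n, dtype=bool)
    guard = 0
    while drop.sum() < target and guard < 10_000:
        guard += 1
        run = max(1, int(rng.geometric(1.0 / clump_scale)))
        run = min(run, target - int(drop.sum()) + run // 2)
        start = int(rng.integers(0, n))
        drop[start : start + run] = True
    keep = ~drop
    # trim overshoot so N shrinks by exactly `target` (±1 from rounding)
    excess = int(drop.sum()) - target
    if excess > 0:
        dropped_idx = np.nonzero(drop)[0]
        keep[dropped_idx[:excess]] = True
    out = cloud.select(keep)
    out.meta.update({"degraded": True, "drop_fraction": drop_fraction, "degrade_seed": seed})
    return out


def rasterize(cloud: PointCloud3D, spacing, shape=None) -> VolumeStack:
    """Write a cloud back into a voxel count grid (inverse of thresholding).

    Voxels covering at least one point get the point count; the grid origin
    is at (0, 0, 0) μm.  Useful for round-trip tests against
    :func:`vasctda.volume_io.threshold_to_points`.
    """
    s = np.asarray(spacing, dtype=float)
    idx = np.floor(cloud.coords / s).astype(int)
    if np.any(idx < 0):
        raise ValueError("rasterize expects non-negative coordinates")
    if shape is None:
        if cloud.n == 0:
            raise ValueError("cannot infer a grid shape from an empty cloud")
        nx, ny, nz = idx.max(axis=0) + 1
        shape = (int(nz), int(ny), int(nx))
    values = np.zeros(shape, dtype=np.int32)
    np.add.at(values, (idx[:, 2], idx[:, 1], idx[:, 0]), 1)
    return VolumeStack(values, tuple(s))
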