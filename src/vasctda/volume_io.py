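"""Classified image volumes and their conversion to physical point clouds.

The upstream pixel classifier exports per-voxel "target signal" probabilities
(HDF5) or raw stacks (TIFF).  Everything downstream of the classifier works on
point clouds in physical micrometre coordinates, so this module owns the
voxel-grid conventions:

* arrays are stored ``(z, y, x)`` (one TIFF page per z-plane, HDF5 datasets
  assumed ``(z, y, x)``);
* voxel spacing is given as ``(sx, sy, sz)`` in μm per voxel;
* a voxel with 0-based index ``(ix, iy, iz)`` has its centre at
  ``((ix + 0.5) sx, (iy + 0.5) sy, (iz + 0.5) sz)`` and all reported
  coordinates are ``(x, y, z)`` μm.

Anisotropic spacing (e.g. 6.45 μm in-plane with 10 μm z-steps from light-sheet
stacks) is supported throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeStack",
    "LabelVolume",
    "PointCloud3D",
    "read_volume",
    "write_volume",
    "threshold_to_points",
    "attach_region_labels",
    "volume_metric",
    "subsample",
    "read_point_cloud",
    "write_point_cloud",
]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(s)}")
    if any(not np.isfinite(v) or v <= 0 for v in s):
        raise ValueError(f"spacing components must be positive and finite, got {s}")
    return s


@dataclass
class VolumeStack:
    """A 3D scalar grid (probabilities or intensities) with voxel spacing.

    ``values`` is indexed ``(z, y, x)``; ``spacing`` is ``(sx, sy, sz)`` μm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.issubdtype(self.values.dtype, np.number):
            raise TypeError(f"volume data must be numeric, got {self.values.dtype}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LabelVolume:
    """Integer region labels on the same grid as an associated :class:`VolumeStack`.

    Label 0 is reserved for "unlabeled".
    """

    labels: np.ndarray
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be integers")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.label_names = dict(self.label_names)

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class PointCloud3D:
    """N points in physical μm coordinates with optional region labels.

    ``coords`` is an ``(N, 3)`` array of ``(x, y, z)`` μm.  ``channel`` is a
    free-text tag naming the stained structure (e.g. ``"aSMA"``, ``"VEcad"``,
    ``"Prox1"``).
    """

    coords: np.ndarray
    region_id: np.ndarray | None = None
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.region_id is not None:
            self.region_id = np.asarray(self.region_id, dtype=int)
            if self.region_id.shape != (len(self.coords),):
                raise ValueError("region_id length must equal the number of points")

    @property
    def n(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return self.n

    def select(self, mask: np.ndarray) -> "PointCloud3D":
        """Subset by boolean mask or index array, keeping labels and channel."""
        region = None if self.region_id is None else self.region_id[mask]
        return PointCloud3D(self.coords[mask], region, self.channel, dict(self.meta))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n == 0:
            raise ValueError("empty point cloud has no bounding box")
        return self.coords.min(axis=0), self.coords.max(axis=0)


# ---------------------------------------------------------------------------
# volume readers / writers
# ---------------------------------------------------------------------------

def read_volume(path, dataset: str | None = None, spacing=None) -> VolumeStack:
    """Read a classified volume from HDF5 or (multi-page) TIFF.

    Parameters
    ----------
    path : str or Path
        ``.h5``/``.hdf5`` file (``dataset`` selects the array; if omitted and
        the file holds a single dataset, that one is used) or a TIFF stack
        interpreted as one page per z-plane.
    spacing : (sx, sy, sz), optional
        Voxel spacing in μm.  Defaults to ``(1, 1, 1)`` with a logged warning,
        since neither format carries calibrated spacing reliably.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5", ".hdf"}:
        import h5py

        with h5py.File(path, "r") as f:
            if dataset is None:
                names: list[str] = []
                f.visit(lambda n: names.append(n) if isinstance(f[n], h5py.Dataset) else None)
                if len(names) != 1:
                    raise ValueError(
                        f"{path} holds {len(names)} datasets {names}; pass dataset="
                    )
                dataset = names[0]
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            values = np.asarray(f[dataset])
    else:
        import tifffile

        values = tifffile.imread(path)
        if values.ndim == 2:
            values = values[None]
    if spacing is None:
        logger.warning("no voxel spacing given for %s; assuming (1, 1, 1) um", path)
        spacing = (1.0, 1.0, 1.0)
    return VolumeStack(values, spacing)


def write_volume(vol: VolumeStack, path, dataset: str = "volume") -> None:
    """Write a volume to HDF5 (``.h5``) or TIFF, inverse of :func:`read_volume`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5", ".hdf"}:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=vol.values)
            f[dataset].attrs["spacing_um"] = vol.spacing
    else:
        import tifffile

        tifffile.imwrite(path, vol.values)


# ---------------------------------------------------------------------------
# point extraction
# ---------------------------------------------------------------------------

def threshold_to_points(vol: VolumeStack, threshold: float, channel: str = "") -> PointCloud3D:
    """One point per voxel with value >= ``threshold``, at voxel centres (μm).

    Hard binarization of the classifier probability map; the threshold is the
    channel-specific cutoff chosen by visual comparison with the raw signal.
    An empty cloud is a valid result.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    iz, iy, ix = np.nonzero(vol.values >= threshold)
    sx, sy, sz = vol.spacing
    coords = np.column_stack([(ix + 0.5) * sx, (iy + 0.5) * sy, (iz + 0.5) * sz])
    return PointCloud3D(coords.reshape(-1, 3), channel=channel)


def attach_region_labels(cloud: PointCloud3D, labels: LabelVolume, spacing) -> PointCloud3D:
    """Populate ``region_id`` from an aligned atlas label grid.

    Each point is mapped back to a voxel index by ``floor(coord / spacing)``;
    points landing on label 0 keep id 0 (unlabeled).  A point outside the grid
    is an error naming the offending point index.
    """
    sx, sy, sz = _as_spacing(spacing)
    nz, ny, nx = labels.labels.shape
    idx = np.floor(cloud.coords / np.array([sx, sy, sz])).astype(int)
    oob = (
        (idx[:, 0] < 0) | (idx[:, 0] >= nx)
        | (idx[:, 1] < 0) | (idx[:, 1] >= ny)
        | (idx[:, 2] < 0) | (idx[:, 2] >= nz)
    )
    if np.any(oob):
        first = int(np.nonzero(oob)[0][0])
        raise IndexError(
            f"point {first} at {tuple(cloud.coords[first])} um maps outside the "
            f"label grid of shape (z,y,x)={labels.labels.shape}"
        )
    region = labels.labels[idx[:, 2], idx[:, 1], idx[:, 0]].astype(int)
    return PointCloud3D(cloud.coords.copy(), region, cloud.channel, dict(cloud.meta))


def volume_metric(obj, spacing=None, threshold: float | None = None) -> tuple[int, float]:
    """Voxel count and physical volume (μm³) of a cloud or thresholded volume.

    For a :class:`PointCloud3D` each point stands for one voxel, so the count
    is ``N`` and the volume ``N * sx * sy * sz`` — the whole-organ "signal
    volume" readout.  For a :class:`VolumeStack`, voxels with
    ``value >= threshold`` (default 0.5) are counted.
    """
    if isinstance(obj, PointCloud3D):
        if spacing is None:
            raise ValueError("spacing required to convert a point count to a volume")
        sx, sy, sz = _as_spacing(spacing)
        return obj.n, obj.n * sx * sy * sz
    if isinstance(obj, VolumeStack):
        thr = 0.5 if threshold is None else threshold
        count = int(np.count_nonzero(obj.values >= thr))
        return count, count * obj.voxel_volume
    raise TypeError(f"expected PointCloud3D or VolumeStack, got {type(obj)!r}")


def subsample(cloud: PointCloud3D, n_max: int, seed: int = 0) -> PointCloud3D:
    """Uniform random subset without replacement of size ``min(N, n_max)``.

    Deterministic for a fixed seed; used to keep the Rips complex tractable on
    whole-organ voxel clouds.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if cloud.n <= n_max:
        return cloud
    rng = np.random.default_rng(seed)
    keep = rng.choice(cloud.n, size=n_max, replace=False)
    keep.sort()
    out = cloud.select(keep)
    out.meta["subsampled_from"] = cloud.n
    out.meta["subsample_seed"] = seed
    return out


# ---------------------------------------------------------------------------
# point-cloud CSV round trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["x_um", "y_um", "z_um", "region_id", "channel"]


def write_point_cloud(cloud: PointCloud3D, path) -> None:
    """Write a cloud as CSV with header ``x_um,y_um,z_um,region_id,channel``."""
    region = cloud.region_id if cloud.region_id is not None else np.zeros(cloud.n, dtype=int)
    df = pd.DataFrame(
        {
            "x_um": cloud.coords[:, 0],
            "y_um": cloud.coords[:, 1],
            "z_um": cloud.coords[:, 2],
            "region_id": region,
            "channel": [cloud.channel] * cloud.n,
        }
    )
    df.to_csv(path, index=False)


def read_point_cloud(path) -> PointCloud3D:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    region = None
    if "region_id" in df.columns and len(df):
        region = df["region_id"].fillna(0).to_numpy(dtype=int)
    channel = ""
    if "channel" in df.columns and len(df):
        channels = df["channel"].fillna("").unique()
        if len(channels) > 1:
            raise ValueError(f"{path}: mixed channels {list(channels)}; split the file")
        channel = str(channels[0])
    return PointCloud3D(coords.reshape(-1, 3), region, channel)
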