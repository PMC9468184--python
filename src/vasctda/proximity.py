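"""Nearest-neighbour distances between two structures (e.g. tumours vs lymphatics).

Distances are computed point-to-point on the thresholded voxel clouds, in μm,
so the readout is "for each source voxel, how far is the nearest target
voxel".  Note the relation is asymmetric: distances from tumours to lymphatic
vessels are not the same distribution as the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volume_io import PointCloud3D

__all__ = ["DistanceSummary", "nn_distances", "summarize"]


@dataclass(frozen=True)
class DistanceSummary:
    """Tukey boxplot five-number summary with 1.5·IQR outlier fences.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme values inside the fences
    ``[q1 − 1.5·IQR, q3 + 1.5·IQR]``; values beyond them are outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def nn_distances(source, target) -> np.ndarray:
    """Euclidean distance from each source point to its nearest target point."""
    src = source.coords if isinstance(source, PointCloud3D) else np.atleast_2d(source)
    tgt = target.coords if isinstance(target, PointCloud3D) else np.atleast_2d(target)
    if len(tgt) == 0:
        raise ValueError("target cloud is empty")
    if len(src) == 0:
        return np.empty(0)
    dist, _ = cKDTree(tgt).query(src, k=1)
    return np.asarray(dist, dtype=float)


def summarize(distances) -> DistanceSummary:
    """Five-number summary of a distance sample."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(d, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = d[(d >= lo_fence) & (d <= hi_fence)]
    outliers = d[(d < lo_fence) | (d > hi_fence)]
    return DistanceSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=tuple(sorted(float(v) for v in outliers)),
        n=int(d.size),
    )
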