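"""Statistical k-NN outlier filter for large-scale discrete noise.

Each point's mean Euclidean distance d̄ᵢ to its k nearest *other* points is
compared with a global threshold

    L = mean(d̄) + σ · std(d̄)        (sample std, n−1 denominator)

and points with d̄ᵢ strictly above L are removed. Sparse points hovering off
the body have inflated d̄ᵢ and fall above L; dense surface points survive.
Defaults k=30, σ=2 follow the parameter study on real sow scenes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import ParameterError


@dataclass
class FilterParams:
    k: int = 30       # neighbor count
    sigma: float = 2.0  # threshold multiplier

    def validate(self, n_points: int | None = None) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if n_points is not None and self.k >= n_points:
            raise ParameterError(
                f"k={self.k} must be smaller than the cloud size {n_points}"
            )
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


@dataclass
class FilterStats:
    """Per-point mean k-NN distances and the derived global threshold."""

    mean_knn_dist: np.ndarray  # d̄ᵢ per point, m
    global_mean: float  # mean of all d̄ᵢ, m
    global_std: float   # sample std of all d̄ᵢ (n−1), m
    threshold: float    # L = mean + σ·std, m


def knn_mean_distances(cloud: PointCloud, k: int) -> np.ndarray:
    """Mean distance from each point to its k nearest other points.

    The query point is excluded from its own neighborhood (self-distance
    would bias the mean toward zero). Equidistant neighbor ties are broken
    by the spatial index deterministically; tied distances leave the mean
    unchanged either way.
    """
    n = len(cloud)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n <= k:
        raise ParameterError(f"cloud size {n} must exceed k={k}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1, workers=-1)
    return dists[:, 1:].mean(axis=1)  # drop the zero self-distance


def filter_stats(mean_dists, sigma: float) -> FilterStats:
    """Global mean / sample std of the d̄ᵢ and the removal threshold L."""
    d = np.asarray(mean_dists, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ParameterError("mean_dists must be a non-empty 1D sequence")
    if d.size < 2:
        raise ParameterError("need at least two points for a sample std")
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    mean = float(d.mean())
    std = float(d.std(ddof=1))
    return FilterStats(d, mean, std, mean + sigma * std)


def statistical_filter(cloud: PointCloud, params: FilterParams | None = None):
    """Remove points whose mean k-NN distance strictly exceeds L.

    Returns ``(kept, removed_mask, stats)``. Equality with L retains the
    point (deletion requires strict excess); survivors keep input order and
    labels.
    """
    params = params or FilterParams()
    params.validate(len(cloud))
    d = knn_mean_distances(cloud, params.k)
    stats = filter_stats(d, params.sigma)
    removed = d > stats.threshold
    return cloud.select(~removed), removed, stats
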