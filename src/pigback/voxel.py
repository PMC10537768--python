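"""Voxel-grid downsampling: regular-cube centroid pooling.

Space is partitioned into cubes of side ``r`` anchored at the cloud's
coordinate minima; every occupied cube is replaced by the centroid of its
points. Cube (i, j, k) covers the half-open box
``[min + i·r, min + (i+1)·r)`` per axis; points exactly on the upper extent
are clamped into the last cube. Flat indices follow

    h = hx + hy·Dx + hz·Dx·Dy

and the output is ordered by ascending h, which makes the result invariant
to input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud
from .errors import ParameterError


@dataclass
class VoxelGrid:
    r: float            # cube side, m
    mins: np.ndarray    # (3,) coordinate minima
    dims: np.ndarray    # (3,) voxel counts per axis, >= 1


def voxel_grid_dims(cloud: PointCloud, r: float) -> VoxelGrid:
    """Grid anchored at the coordinate minima with ceil((max-min)/r) cubes."""
    if r <= 0:
        raise ParameterError("voxel size r must be positive")
    if len(cloud) == 0:
        raise ParameterError("cannot grid an empty cloud")
    mins = cloud.points.min(axis=0)
    maxs = cloud.points.max(axis=0)
    dims = np.maximum(np.ceil((maxs - mins) / r).astype(np.int64), 1)
    return VoxelGrid(float(r), mins, dims)


def voxel_index(point, grid: VoxelGrid) -> int:
    """Flat voxel index h of a point inside the grid bounds."""
    point = np.asarray(point, dtype=float)
    if np.any(point < grid.mins) or np.any(point > grid.mins + grid.dims * grid.r):
        raise ParameterError(f"point {point} lies outside the voxel grid")
    idx = np.floor((point - grid.mins) / grid.r).astype(np.int64)
    idx = np.minimum(idx, grid.dims - 1)  # clamp the exact upper boundary
    hx, hy, hz = idx
    return int(hx + hy * grid.dims[0] + hz * grid.dims[0] * grid.dims[1])


def voxel_downsample(cloud: PointCloud, r: float):
    """One centroid per occupied voxel, ordered by ascending flat index.

    Labels, when present, are pooled by majority vote within each voxel
    (ties become ``unknown``). Returns ``(downsampled cloud, grid)``.
    """
    grid = voxel_grid_dims(cloud, r)
    idx = np.floor((cloud.points - grid.mins) / grid.r).astype(np.int64)
    idx = np.minimum(idx, grid.dims - 1)
    h = idx[:, 0] + idx[:, 1] * grid.dims[0] + idx[:, 2] * grid.dims[0] * grid.dims[1]

    # canonical order (voxel, then coordinates) so centroid summation is
    # bitwise identical under any input permutation
    order = np.lexsort((cloud.points[:, 2], cloud.points[:, 1],
                        cloud.points[:, 0], h))
    h_sorted = h[order]
    uniq, starts = np.unique(h_sorted, return_index=True)
    counts = np.diff(np.append(starts, len(h_sorted)))
    sums = np.add.reduceat(cloud.points[order], starts, axis=0)
    centroids = sums / counts[:, None]

    labels = None
    if cloud.labels is not None:
        lab_sorted = cloud.labels[order]
        labels = np.empty(len(uniq), dtype=cloud.labels.dtype)
        for i, (s, c) in enumerate(zip(starts, counts)):
            vals, vc = np.unique(lab_sorted[s:s + c], return_counts=True)
            top = vc == vc.max()
            labels[i] = vals[top][0] if top.sum() == 1 else "unknown"
    return PointCloud(centroids, labels), grid
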