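"""Density-based clustering (DBSCAN) and pig-cluster selection.

The clustering follows the classical seeded-expansion algorithm exactly:
points are scanned in index order; the first unvisited core point seeds a
new cluster (ids 1, 2, ... in discovery order; 0 is noise) and the cluster
absorbs everything density-reachable from it. A point first marked noise is
re-assigned as a *border* point when a later expansion reaches it; a border
point within Eps of cores of several clusters belongs to the earliest-created
of them — the only order-dependence the algorithm has, and it is resolved by
scan order, so results are reproducible for a given point ordering.

Instead of a literal point-by-point expansion loop (quadratic bookkeeping in
Python), the same labeling is computed vectorized:

1. neighborhood sizes via a k-d tree (the ε-ball includes the point itself,
   counted against MinPts);
2. core points = neighborhoods of size >= MinPts; clusters = connected
   components of the core-core ε-graph, numbered by their minimal core index
   (equivalent to seed discovery order);
3. border points attach to the earliest-numbered cluster owning a core
   within Eps; everything else is noise.

Equivalence with the literal expansion is enforced by a brute-force oracle
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import ParameterError, SegmentationError


@dataclass
class DBSCANParams:
    eps: float = 0.02   # neighborhood radius, m
    min_pts: int = 10   # minimum ε-neighborhood size (incl. the point itself)

    def validate(self) -> None:
        if self.eps <= 0:
            raise ParameterError("eps must be positive")
        if self.min_pts < 1:
            raise ParameterError("min_pts must be >= 1")


@dataclass
class ClusterLabeling:
    """Per-point cluster ids (0 = noise, 1..K) and core/border/noise roles."""

    cluster_id: np.ndarray  # int, shape (n,)
    role: np.ndarray        # '<U6': core | border | noise

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max(initial=0))

    def cluster_sizes(self) -> np.ndarray:
        """Sizes of clusters 1..K (index 0 unused)."""
        return np.bincount(self.cluster_id, minlength=self.n_clusters + 1)


def region_query(cloud: PointCloud, index: int, eps: float) -> np.ndarray:
    """Indices of all points within Euclidean distance eps of point ``index``.

    The query point itself is included (distance 0).
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    n = len(cloud)
    if not 0 <= index < n:
        raise ParameterError(f"index {index} out of range for cloud of size {n}")
    d = np.linalg.norm(cloud.points - cloud.points[index], axis=1)
    return np.flatnonzero(d <= eps)


def dbscan(cloud: PointCloud, params: DBSCANParams | None = None) -> ClusterLabeling:
    """Cluster a cloud; see the module docstring for the exact semantics."""
    params = params or DBSCANParams()
    params.validate()
    n = len(cloud)
    if n == 0:
        raise ParameterError("cannot cluster an empty cloud")

    tree = cKDTree(cloud.points)
    counts = tree.query_ball_point(cloud.points, params.eps,
                                   return_length=True, workers=-1)
    core = counts >= params.min_pts
    core_idx = np.flatnonzero(core)

    cluster_id = np.zeros(n, dtype=np.int64)
    role = np.full(n, "noise", dtype="<U6")
    if len(core_idx) == 0:
        return ClusterLabeling(cluster_id, role)

    core_tree = cKDTree(cloud.points[core_idx])
    pairs = core_tree.query_pairs(params.eps, output_type="ndarray")
    m = len(core_idx)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
        shape=(m, m),
    )
    n_comp, comp = sparse.csgraph.connected_components(adj, directed=False)

    # number clusters by the smallest original index of any of their cores:
    # identical to the order a seeded index-order scan would create them
    first_core = np.full(n_comp, n, dtype=np.int64)
    np.minimum.at(first_core, comp, core_idx)
    rank = np.empty(n_comp, dtype=np.int64)
    rank[np.argsort(first_core)] = np.arange(1, n_comp + 1)
    cluster_id[core_idx] = rank[comp]
    role[core_idx] = "core"

    border_idx = np.flatnonzero(~core)
    if len(border_idx):
        hits = core_tree.query_ball_point(cloud.points[border_idx], params.eps,
                                          workers=-1)
        for bi, neigh in zip(border_idx, hits):
            if neigh:
                cluster_id[bi] = cluster_id[core_idx[neigh]].min()
                role[bi] = "border"
    return ClusterLabeling(cluster_id, role)


def estimate_floor_level(cloud: PointCloud, labeling: ClusterLabeling,
                         floor_margin: float) -> float:
    """Floor height: modal z of the largest cluster when it is flat enough.

    In an overhead passage scene the floor is usually the largest cluster;
    its modal height (1 cm histogram) estimates the floor level. If that
    cluster's z-spread exceeds ``floor_margin`` (it is not a flat structure),
    fall back to the 1st percentile of all heights.
    """
    z = cloud.points[:, 2]
    sizes = labeling.cluster_sizes()
    if labeling.n_clusters >= 1:
        biggest = int(np.argmax(sizes[1:])) + 1
        zc = z[labeling.cluster_id == biggest]
        spread = zc.max() - zc.min()
        if spread == 0:
            return float(zc[0])
        if spread < floor_margin:
            hist, edges = np.histogram(zc, bins=max(int(spread / 0.01), 1))
            i = int(np.argmax(hist))
            return float((edges[i] + edges[i + 1]) / 2)
    return float(np.percentile(z, 1))


def select_pig_cluster(cloud: PointCloud, labeling: ClusterLabeling,
                       min_size: int = 200, floor_margin: float = 0.1) -> PointCloud:
    """Pick the elevated cluster that is the pig.

    Among clusters of at least ``min_size`` points whose mean height exceeds
    the floor level by ``floor_margin``, the one with the greatest mean
    height is returned. Selection is by elevation, not raw size: in an
    overhead scene the floor itself is typically the largest cluster.
    """
    if len(cloud) != len(labeling.cluster_id):
        raise ParameterError("labeling does not match cloud size")
    if labeling.n_clusters == 0:
        raise SegmentationError("no clusters found; nothing to select")
    floor_z = estimate_floor_level(cloud, labeling, floor_margin)
    z = cloud.points[:, 2]
    sizes = labeling.cluster_sizes()
    best, best_mean = None, -np.inf
    for cid in range(1, labeling.n_clusters + 1):
        if sizes[cid] < min_size:
            continue
        mean_z = z[labeling.cluster_id == cid].mean()
        if mean_z > floor_z + floor_margin and mean_z > best_mean:
            best, best_mean = cid, mean_z
    if best is None:
        raise SegmentationError(
            f"no cluster of >= {min_size} points rises more than "
            f"{floor_margin} m above the floor level {floor_z:.3f} m"
        )
    return cloud.select(labeling.cluster_id == best)
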