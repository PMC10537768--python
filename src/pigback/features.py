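"""Back body-size features and their correlation analysis.

Six parameters summarize the trimmed, aligned back cloud:

* ``envelope_volume`` / ``envelope_area`` — volume and surface area of the
  3D convex hull (the "minimum envelope" of the back);
* ``projection_area`` — shoelace area of the concave planar outline (the
  outline, not the hull, so the head/tail trim is reflected);
* ``shoulder_width`` / ``belly_width`` / ``hip_width`` — Euclidean
  separations L1, L2, L3 of three key-point pairs on the outline.

The key points are taken by splitting the body's x-range into three equal
thirds and pairing, within each third, the outline vertex of maximal y with
the vertex of minimal y; pairs are reported anterior (head end, +x) to
posterior. Widths scale as s, areas as s², volume as s³ under uniform
scaling, and all six are invariant to translation and (fixed) alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .cloud import PointCloud
from .errors import GeometryError, ParameterError
from .segmentation import Outline2D, convex_hull_2d, extract_outline, project_xy


@dataclass
class BackFeatures:
    envelope_volume: float   # m^3
    envelope_area: float     # m^2
    projection_area: float   # m^2
    shoulder_width: float    # m
    belly_width: float       # m
    hip_width: float         # m

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)


@dataclass
class Keypoints:
    """Three (max-y, min-y) outline vertex pairs, anterior to posterior."""

    pairs: np.ndarray  # shape (3, 2, 2)


def extract_keypoints(outline: Outline2D, head_direction: str = "+x") -> Keypoints:
    """Extremal-y vertex pairs in the anterior / middle / posterior thirds."""
    v = outline.vertices
    xs = v[:, 0]
    if len(np.unique(xs)) < 3:
        raise GeometryError("outline spans fewer than 3 distinct x positions")
    lo, hi = xs.min(), xs.max()
    edges = np.array([lo, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3, hi])
    pairs = []
    thirds = (2, 1, 0) if head_direction == "+x" else (0, 1, 2)
    for t in thirds:  # anterior third first
        mask = (xs >= edges[t]) & (xs <= edges[t + 1])
        if not mask.any():
            raise GeometryError("an x-third of the outline holds no vertices")
        sel = np.flatnonzero(mask)
        center = (edges[t] + edges[t + 1]) / 2
        # ties in extremal y resolve to the vertex nearest the third's center
        def pick(extreme):
            yv = v[sel, 1]
            tied = sel[yv == extreme]
            off = np.abs(v[tied, 0] - center)
            tied = tied[off == off.min()]
            return tied[np.argmin(v[tied, 0])]
        top = pick(v[sel, 1].max())
        bot = pick(v[sel, 1].min())
        pairs.append([v[top], v[bot]])
    return Keypoints(np.asarray(pairs))


def widths(kp: Keypoints):
    """(L1, L2, L3): Euclidean separation of each key-point pair (m)."""
    d = np.linalg.norm(kp.pairs[:, 0] - kp.pairs[:, 1], axis=1)
    return float(d[0]), float(d[1]), float(d[2])


def projection_area(outline: Outline2D) -> float:
    """Shoelace area of the (possibly concave) outline polygon."""
    area = outline.signed_area
    if area <= 0:
        raise GeometryError("outline polygon is not counter-clockwise")
    return float(area)


def envelope_3d(cloud: PointCloud):
    """(volume, surface area) of the 3D convex hull of the cloud."""
    if len(cloud) < 4:
        raise GeometryError("3D hull needs at least 4 points")
    try:
        hull = ConvexHull(cloud.points)
    except (QhullError, ValueError) as exc:
        raise GeometryError(f"degenerate cloud (coplanar points?): {exc}")
    return float(hull.volume), float(hull.area)


def extract_back_features(cloud: PointCloud, alpha: float | None = None,
                          head_direction: str = "+x") -> BackFeatures:
    """The six back parameters of a trimmed, aligned back cloud."""
    pts2d = project_xy(cloud)
    outline = extract_outline(pts2d, alpha)
    kp = extract_keypoints(outline, head_direction)
    l1, l2, l3 = widths(kp)
    volume, area = envelope_3d(cloud)
    return BackFeatures(
        envelope_volume=volume,
        envelope_area=area,
        projection_area=projection_area(outline),
        shoulder_width=l1,
        belly_width=l2,
        hip_width=l3,
    )


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation of two equal-length lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("pearson needs two equal-length sequences of >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def correlation_table(records) -> np.ndarray:
    """6x6 Pearson matrix across a list of BackFeatures records."""
    if len(records) < 3:
        raise ParameterError("correlation table needs >= 3 records")
    mat = np.array([r.as_array() for r in records])
    for j in range(mat.shape[1]):
        if np.ptp(mat[:, j]) == 0:
            raise ParameterError(
                f"feature column {j} has zero variance; correlation undefined"
            )
    return np.corrcoef(mat, rowvar=False)
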