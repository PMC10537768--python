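"""Plane projection, alignment, outline, sag profile and head/tail split.

After denoising, the pig cloud is projected to the horizontal plane and
rotated about z so its minimum-area bounding rectangle is axis-parallel with
the long (body) axis along x. A concave outline of the projection is built
as an alpha-shape boundary; its convex hull is the minimum envelope polygon.
The *sag* of each outline vertex — perpendicular distance to the hull edge
spanning it — measures how deep the contour dips inward. Deep sags mark the
neck and tail-root notches; cutting perpendicular to the body axis at those
notches removes the head and tail, whose changing pose would otherwise
corrupt the back measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .cloud import PointCloud
from .errors import GeometryError, ParameterError, SegmentationError


@dataclass
class Outline2D:
    """Simple closed CCW polygon of outline vertices (implicitly closed)."""

    vertices: np.ndarray  # (m, 2)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise GeometryError("outline needs >= 3 planar vertices")
        self.vertices = v

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ConvexPolygon:
    """CCW convex polygon; ``indices`` point into the source vertex array."""

    vertices: np.ndarray  # (h, 2)
    indices: np.ndarray   # (h,) indices into the input point set


@dataclass
class SagProfile:
    """Per-outline-vertex concavity depth and spanning hull edge."""

    depth: np.ndarray       # (m,) perpendicular distance to spanning hull edge
    spanning_edge: np.ndarray  # (m,) hull-edge id each vertex projects onto


@dataclass
class SplitResult:
    head_cut_x: float
    tail_cut_x: float
    cloud: PointCloud
    warnings: list = field(default_factory=list)
    candidates: np.ndarray | None = None  # (k, 2) candidate notch vertices


def project_xy(cloud: PointCloud) -> np.ndarray:
    """Drop z: the planar (x, y) coordinates of every point."""
    if len(cloud) == 0:
        raise ParameterError("cannot project an empty cloud")
    return cloud.points[:, :2].copy()


def min_area_rectangle_angle(points2d: np.ndarray):
    """Orientation (radians) and area of the minimum-area enclosing rectangle.

    Rotating-calipers over convex-hull edge directions: the optimal rectangle
    has a side collinear with some hull edge. Returns ``(angle, area)`` where
    rotating the points by ``-angle`` makes the rectangle axis-parallel.
    """
    try:
        hull = ConvexHull(points2d)
    except (QhullError, ValueError) as exc:
        raise GeometryError(f"degenerate projection (collinear points?): {exc}")
    hv = points2d[hull.vertices]
    edges = np.roll(hv, -1, axis=0) - hv
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    best_angle, best_area = 0.0, np.inf
    for phi in angles:
        c, s = np.cos(-phi), np.sin(-phi)
        rx = hv[:, 0] * c - hv[:, 1] * s
        ry = hv[:, 0] * s + hv[:, 1] * c
        area = (rx.max() - rx.min()) * (ry.max() - ry.min())
        if area < best_area - 1e-15:
            best_angle, best_area = phi, area
    return best_angle, best_area


def align_horizontal(cloud: PointCloud):
    """Rotate about z so the min-area bounding rectangle is axis-parallel.

    The rotation is rigid (about the projection centroid) and chosen so the
    rectangle's long side lies along x; the applied angle is returned in
    degrees, normalized to (−90°, 90°].
    """
    pts2d = project_xy(cloud)
    phi, _ = min_area_rectangle_angle(pts2d)
    theta = -phi  # rotation that maps the optimal edge direction onto x

    def rotate(points, ang):
        c, s = np.cos(ang), np.sin(ang)
        out = points.copy()
        ctr = pts2d.mean(axis=0)
        dx, dy = points[:, 0] - ctr[0], points[:, 1] - ctr[1]
        out[:, 0] = ctr[0] + dx * c - dy * s
        out[:, 1] = ctr[1] + dx * s + dy * c
        return out

    rot = rotate(cloud.points, theta)
    if np.ptp(rot[:, 0]) < np.ptp(rot[:, 1]):  # long side must end up along x
        theta += np.pi / 2
        rot = rotate(cloud.points, theta)
    deg = np.degrees(theta)
    deg = (deg + 90.0) % 180.0 - 90.0
    if deg <= -90.0:
        deg += 180.0
    return PointCloud(rot, cloud.labels), float(deg)


def _circumradius(p0, p1, p2):
    a = np.linalg.norm(p1 - p0, axis=-1)
    b = np.linalg.norm(p2 - p1, axis=-1)
    c = np.linalg.norm(p0 - p2, axis=-1)
    s = (a + b + c) / 2
    area_sq = np.maximum(s * (s - a) * (s - b) * (s - c), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (4.0 * np.sqrt(area_sq))
    return np.where(area_sq > 0, r, np.inf)


def _points_in_polygon(points, poly):
    """Vectorized even-odd (crossing-number) point-in-polygon test."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        crosses = (ay > y) != (by > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (y - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (x < xint)
    return inside


def default_alpha(points2d: np.ndarray) -> float:
    """3x the median nearest-neighbor spacing of the planar point set."""
    tree = cKDTree(points2d)
    d, _ = tree.query(points2d, k=2, workers=-1)
    return 3.0 * float(np.median(d[:, 1]))


def extract_outline(points2d: np.ndarray, alpha: float | None = None) -> Outline2D:
    """Concave boundary polygon of a dense planar point set (alpha shape).

    Delaunay triangles with circumradius <= alpha are kept; the boundary of
    their union, traced into a closed loop, is the outline. For convex point
    sets the outline degenerates to (approximately) the convex hull. An
    alpha too small to connect the set into one boundary raises a geometry
    error suggesting a larger value.
    """
    points2d = np.asarray(points2d, dtype=float)
    if len(points2d) < 10:
        raise ParameterError("outline extraction needs at least 10 points")
    if alpha is None:
        alpha = default_alpha(points2d)
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    try:
        tri = Delaunay(points2d)
    except (QhullError, ValueError) as exc:
        raise GeometryError(f"triangulation failed: {exc}")
    simp = tri.simplices
    p = points2d
    keep = _circumradius(p[simp[:, 0]], p[simp[:, 1]], p[simp[:, 2]]) <= alpha
    simp = simp[keep]
    if len(simp) == 0:
        raise GeometryError(f"alpha={alpha:.4g} keeps no triangles; increase alpha")

    # boundary edges appear in exactly one kept triangle
    edges = np.sort(np.vstack([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [2, 0]]]),
                    axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) < 3:
        raise GeometryError(f"alpha={alpha:.4g} yields no boundary; increase alpha")

    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))

    unused = {tuple(e) for e in boundary.tolist()}
    loops = []
    while unused:
        a, b = next(iter(unused))
        loop = [a, b]
        unused.discard((a, b))
        while True:
            cur, prev = loop[-1], loop[-2]
            nxt = None
            for cand in adj[cur]:
                key = (cur, cand) if cur < cand else (cand, cur)
                if key in unused:
                    nxt = cand
                    unused.discard(key)
                    break
            if nxt is None:
                break
            if nxt == loop[0]:
                break
            loop.append(nxt)
        if len(loop) >= 3:
            loops.append(loop)
    if not loops:
        raise GeometryError(f"could not trace a boundary loop at alpha={alpha:.4g}")

    def loop_area(idx):
        v = points2d[idx]
        x, y = v[:, 0], v[:, 1]
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    outer = max(loops, key=lambda lp: abs(loop_area(lp)))
    verts = points2d[outer]
    if loop_area(outer) < 0:
        verts = verts[::-1]

    inside = _points_in_polygon(points2d, verts)
    # points on the boundary may fail the strict crossing test; count them in
    on_boundary = np.zeros(len(points2d), dtype=bool)
    on_boundary[outer] = True
    coverage = np.mean(inside | on_boundary)
    if coverage < 0.99:
        raise GeometryError(
            f"outline at alpha={alpha:.4g} contains only {coverage:.1%} of the "
            "points (disconnected shape?); increase alpha"
        )
    return Outline2D(verts)


def convex_hull_2d(points2d: np.ndarray) -> ConvexPolygon:
    """Minimal CCW convex polygon of a planar set (extreme vertices only)."""
    points2d = np.asarray(points2d, dtype=float)
    if len(points2d) < 3:
        raise GeometryError("convex hull needs >= 3 points")
    try:
        hull = ConvexHull(points2d)
    except (QhullError, ValueError) as exc:
        raise GeometryError(f"degenerate point set (collinear?): {exc}")
    return ConvexPolygon(points2d[hull.vertices], hull.vertices.astype(np.int64))


def sag_depths(outline: Outline2D, hull: ConvexPolygon) -> SagProfile:
    """Perpendicular distance of each outline vertex to its spanning hull edge.

    Outline vertices between two consecutive hull vertices (in traversal
    order) project onto the hull edge joining them; hull vertices get zero.
    """
    m = len(outline.vertices)
    hidx = np.sort(hull.indices)
    if hidx.max(initial=0) >= m or len(hidx) < 3:
        raise ParameterError("hull does not index into the outline vertices")
    depth = np.zeros(m)
    edge_id = np.full(m, -1, dtype=np.int64)
    v = outline.vertices
    for e, (i0, i1) in enumerate(zip(hidx, np.roll(hidx, -1))):
        a, b = v[i0], v[i1 % m]
        ab = b - a
        norm = np.linalg.norm(ab)
        span = np.arange(i0, i1 if i1 > i0 else i1 + m)[1:] % m
        edge_id[i0] = e
        if norm == 0 or len(span) == 0:
            continue
        rel = v[span] - a
        depth[span] = np.abs(ab[0] * rel[:, 1] - ab[1] * rel[:, 0]) / norm
        edge_id[span] = e
    return SagProfile(depth, edge_id)


def _cyclic_local_maxima(values: np.ndarray, minimum: float) -> np.ndarray:
    """Indices of cyclic local maxima >= minimum; plateaus yield one index.

    Runs of equal values are merged; a run is a maximum when both adjacent
    runs are lower. One candidate per notch, however wide, instead of every
    deep vertex.
    """
    m = len(values)
    change = np.flatnonzero(values != np.roll(values, 1))
    if len(change) == 0:
        return np.empty(0, dtype=np.int64)  # constant profile: no maxima
    run_starts = change
    run_vals = values[run_starts]
    k = len(run_starts)
    out = []
    for r in range(k):
        if run_vals[r] < minimum:
            continue
        if run_vals[r] > run_vals[(r - 1) % k] and \
                run_vals[r] > run_vals[(r + 1) % k]:
            start = run_starts[r]
            end = run_starts[(r + 1) % k]
            length = (end - start) % m or m
            out.append((start + length // 2) % m)
    return np.asarray(sorted(out), dtype=np.int64)


def split_head_tail(cloud: PointCloud, sag_min: float = 0.03,
                    head_direction: str = "+x",
                    alpha: float | None = None) -> SplitResult:
    """Trim head and tail off an aligned cloud at its deepest contour notches.

    Candidate split points are, per contour notch (maximal chain of outline
    vertices under one hull edge), the deepest-sag vertex, kept if its depth
    reaches ``sag_min``. With the body axis along x and the head direction
    known, the dividing axis is the vertical line through the projection
    centroid: the head cut is the candidate *closest* to that axis on the
    head side, the tail cut the candidate *furthest* from it on the tail
    side. Sides lacking a candidate stay uncut (with a recorded warning).
    """
    if sag_min <= 0:
        raise ParameterError("sag_min must be positive")
    if head_direction not in ("+x", "-x"):
        raise ParameterError("head_direction must be '+x' or '-x'")
    pts2d = project_xy(cloud)
    outline = extract_outline(pts2d, alpha)
    hull = convex_hull_2d(outline.vertices)
    sag = sag_depths(outline, hull)

    candidates = outline.vertices[_cyclic_local_maxima(sag.depth, sag_min)]
    candidates = np.asarray(candidates).reshape(-1, 2)

    cx = pts2d[:, 0].mean()
    sign = 1.0 if head_direction == "+x" else -1.0
    offsets = (candidates[:, 0] - cx) * sign if len(candidates) else np.empty(0)
    notes = []

    head_side = offsets > 0
    if head_side.any():
        head_cut = float(candidates[head_side][np.argmin(offsets[head_side]), 0])
    else:
        head_cut = np.inf * sign
        notes.append("no head-side notch deeper than sag_min; head left uncut")
    tail_side = offsets < 0
    if tail_side.any():
        tail_cut = float(candidates[tail_side][np.argmin(offsets[tail_side]), 0])
    else:
        tail_cut = -np.inf * sign
        notes.append("no tail-side notch deeper than sag_min; tail left uncut")

    lo, hi = min(head_cut, tail_cut), max(head_cut, tail_cut)
    keep = (cloud.points[:, 0] > lo) & (cloud.points[:, 0] < hi)
    if not keep.any():
        raise SegmentationError("head/tail trim removed every point")
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return SplitResult(head_cut, tail_cut, cloud.select(keep), notes, candidates)
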