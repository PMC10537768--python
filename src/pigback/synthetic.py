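"""Synthetic overhead pig scenes with known labels and ground-truth weight.

The generator emulates what a downward-looking depth camera mounted ~2.5 m
above a weighing passage sees, expressed directly as heights:

* a planar floor patch at z ≈ 0 (passage 1.7 m wide);
* the camera-visible back of a sow: the upper part of a half-superellipsoid
  sampled on an (x, y) grid at the sensor's ground-sampling pitch, apex at
  ``body_height``, clipped below a ground clearance (the flanks below belly
  height are occluded in an overhead view — the animal stands on its legs);
* a tapered head lobe beyond the +x torso end and a shorter tail lobe beyond
  the −x end, both overlapping the torso surface (so density clustering sees
  one connected body) and both narrower than the torso, which carves the
  concave neck/tail notches that the sag-based splitter looks for;
* two noise populations mirroring the field taxonomy: sparse *large-scale*
  outliers hovering around the body with a guaranteed clearance from every
  surface point, and small dense *small-scale* clusters offset from the body.

Every surface coordinate gets Gaussian jitter. Ground-truth weight follows a
calibrated affine allometric rule on the dimension product L·W·H (see
:func:`allometric_weight`) with multiplicative Gaussian noise, so that the
extreme body dimensions of the default ranges map exactly onto the 190–300 kg
herd range. All randomness is owned by a single seeded generator: the same
seed reproduces a scene bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, SceneGroundTruth
from .errors import ParameterError

#: Herd weight range the allometric rule is calibrated to, kg.
WEIGHT_RANGE = (190.0, 300.0)


@dataclass
class SceneParams:
    """Geometry, sampling and noise parameters of one synthetic scene.

    Dimension fields set to ``None`` are drawn uniformly from their range
    using the scene seed; fixed values are used as-is.
    """

    # body dimension ranges, metres
    body_length_range: tuple = (1.5, 1.9)
    body_width_range: tuple = (0.45, 0.60)
    body_height_range: tuple = (0.50, 0.65)
    body_length: Optional[float] = None
    body_width: Optional[float] = None
    body_height: Optional[float] = None
    # scene geometry
    floor_size: tuple = (2.5, 1.7)  # (x extent, y extent = passage width), m
    clearance: float = 0.30  # lowest visible body height, m
    head_length: float = 0.25  # protrusion beyond the +x torso end, m
    tail_length: float = 0.12  # protrusion beyond the -x torso end, m
    head_width_frac: float = 0.45  # head footprint width as fraction of body width
    tail_width_frac: float = 0.22
    lobe_overlap: float = 0.06  # head/tail overlap into the torso footprint, m
    shape_exponent: float = 2.5  # superellipsoid exponent of the torso
    # sampling / noise
    pitch: float = 0.007  # surface grid pitch, m (~640x480 sensor at 2.5 m)
    jitter_std: float = 0.003  # coordinate noise std, m
    n_outliers_large: int = 300
    outlier_clearance_pitches: float = 5.0  # min dist to surface, in pitches
    n_small_clusters: int = 5
    cluster_size: int = 40
    cluster_std: float = 0.01  # m
    cluster_offset: float = 0.1  # min distance of blob centers from the body, m
    # weight rule
    weight_cv: float = 0.03  # multiplicative noise CV on true weight
    seed: int = 0

    def validate(self) -> None:
        lengths = [
            *self.body_length_range, *self.body_width_range,
            *self.body_height_range, *self.floor_size,
            self.head_length, self.tail_length, self.clearance,
            self.pitch, self.cluster_std, self.cluster_offset,
        ]
        if any(v <= 0 for v in lengths):
            raise ParameterError("all scene lengths must be positive")
        if self.pitch >= self.body_width_range[0] / 10:
            raise ParameterError(
                f"pitch {self.pitch} too coarse: must be < body_width/10"
            )
        if self.weight_cv < 0:
            raise ParameterError("weight_cv must be non-negative")
        if self.jitter_std < 0:
            raise ParameterError("jitter_std must be non-negative")
        for lo, hi in (self.body_length_range, self.body_width_range,
                       self.body_height_range):
            if lo > hi:
                raise ParameterError("dimension range lower bound exceeds upper")
        if min(self.body_height_range) <= self.clearance:
            raise ParameterError("body_height must exceed the ground clearance")
        if self.n_outliers_large < 0 or self.n_small_clusters < 0:
            raise ParameterError("noise counts must be non-negative")


def allometric_weight(length, width, height, params: SceneParams | None = None,
                      rng=None):
    """Weight in kg from body dimensions: affine in the product L·W·H.

    The coefficients are solved so the smallest and largest configurations of
    the parameter ranges land exactly on the calibrated herd range
    (190–300 kg by default); no single multiplicative coefficient can do that
    because the dimension-product range and the weight range are not
    proportional. With ``rng`` given and ``weight_cv > 0`` a multiplicative
    Gaussian factor (1 + ε), ε ~ N(0, CV²), is applied.
    """
    params = params or SceneParams()
    lo = (params.body_length_range[0] * params.body_width_range[0]
          * params.body_height_range[0])
    hi = (params.body_length_range[1] * params.body_width_range[1]
          * params.body_height_range[1])
    w_lo, w_hi = WEIGHT_RANGE
    slope = (w_hi - w_lo) / (hi - lo)
    intercept = w_lo - slope * lo
    w = intercept + slope * (length * width * height)
    if rng is not None and params.weight_cv > 0:
        w *= 1.0 + params.weight_cv * rng.standard_normal()
    return float(w)


def _superellipse_halfwidth(x, cx, ax, b, e):
    """Half-width in y of the footprint |(x-cx)/ax|^e + |y/b|^e = 1."""
    t = 1.0 - np.abs((x - cx) / ax) ** e
    return b * np.maximum(t, 0.0) ** (1.0 / e)


def _lobe_surface(params, cx, ax, by, z0, zc, e, pitch, slope_max=3.5):
    """Grid-sample the camera-visible upper surface of a superellipsoid lobe.

    Points where the surface slope exceeds ``slope_max`` (incidence beyond
    ~74° for a camera straight above) are dropped: grazing returns are lost
    on real depth sensors, and grid sampling would place such points at
    unphysically sparse 3D density.
    """
    xs = np.arange(cx - ax, cx + ax + pitch / 2, pitch)
    ys = np.arange(-by, by + pitch / 2, pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    def height(px, py):
        rho = np.abs((px - cx) / ax) ** e + np.abs(py / by) ** e
        return z0 + zc * np.maximum(1.0 - rho, 0.0) ** (1.0 / e)

    rho = np.abs((gx - cx) / ax) ** e + np.abs(gy / by) ** e
    inside = rho < 1.0
    gx, gy = gx[inside], gy[inside]
    d = pitch / 10
    slope = np.hypot((height(gx + d, gy) - height(gx - d, gy)) / (2 * d),
                     (height(gx, gy + d) - height(gx, gy - d)) / (2 * d))
    keep = slope <= slope_max
    return np.column_stack([gx[keep], gy[keep], height(gx, gy)[keep]])


def generate_pig_scene(params: SceneParams | None = None, seed=None):
    """Build one labeled scene; returns ``(PointCloud, SceneGroundTruth)``.

    The cloud is the concatenation of floor, torso, head, tail, large-scale
    outliers and small-scale noise blobs, each carrying its label. Point
    order within a block follows grid order; downstream stages must not rely
    on it.
    """
    params = params or SceneParams()
    if seed is not None:
        params = replace(params, seed=seed)
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params.pitch

    def draw(fixed, rng_range):
        return fixed if fixed is not None else float(rng.uniform(*rng_range))

    L = draw(params.body_length, params.body_length_range)
    W = draw(params.body_width, params.body_width_range)
    H = draw(params.body_height, params.body_height_range)
    if H <= params.clearance:
        raise ParameterError("body_height must exceed the ground clearance")
    z0 = params.clearance
    a, b, c = L / 2, W / 2, H - z0
    e = params.shape_exponent

    fx, fy = params.floor_size
    xs = np.arange(-fx / 2, fx / 2 + p / 2, p)
    ys = np.arange(-fy / 2, fy / 2 + p / 2, p)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    floor = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])

    torso = _lobe_surface(params, 0.0, a, b, z0, c, e, p)

    # head / tail lobes: narrower and lower than the torso, overlapping it so
    # the surfaces intersect (density-connected), protruding beyond its ends
    ov = params.lobe_overlap
    ax_h = (params.head_length + ov) / 2
    head = _lobe_surface(params, a + (params.head_length - ov) / 2, ax_h,
                         params.head_width_frac * W / 2, z0, 0.55 * c, 2.0, p)
    ax_t = (params.tail_length + ov) / 2
    tail = _lobe_surface(params, -a - (params.tail_length - ov) / 2, ax_t,
                         params.tail_width_frac * W / 2, z0, 0.45 * c, 2.0, p)

    surface = np.vstack([floor, torso, head, tail])
    surface = surface + rng.normal(0.0, params.jitter_std, surface.shape)
    n_floor, n_torso, n_head = len(floor), len(torso), len(head)
    body = surface[n_floor:]

    surf_tree = cKDTree(surface)
    body_tree = cKDTree(body)

    # large-scale outliers: uniform in the body bounding box dilated 0.3 m,
    # kept only if farther than `outlier_clearance_pitches` x pitch from any
    # surface point (gives the statistical filter an unambiguous target)
    lo = body.min(axis=0) - 0.3
    hi = body.max(axis=0) + 0.3
    lo[2] = max(lo[2], 0.05)
    min_d = params.outlier_clearance_pitches * p
    outliers = np.empty((0, 3))
    while len(outliers) < params.n_outliers_large:
        cand = rng.uniform(lo, hi, size=(4 * params.n_outliers_large, 3))
        d, _ = surf_tree.query(cand, k=1)
        cand = cand[d >= min_d]
        outliers = np.vstack([outliers, cand])
    outliers = outliers[: params.n_outliers_large]

    # small-scale noise: dense Gaussian blobs with centers offset >= 0.1 m
    # from the body and kept above the floor plane
    blobs = []
    while len(blobs) < params.n_small_clusters:
        cand = rng.uniform(lo, hi, size=(max(8, 4 * params.n_small_clusters), 3))
        cand[:, 2] = rng.uniform(0.1, hi[2], size=len(cand))
        d, _ = body_tree.query(cand, k=1)
        for ctr in cand[d >= params.cluster_offset]:
            if len(blobs) < params.n_small_clusters:
                blobs.append(ctr + rng.normal(0, params.cluster_std,
                                              (params.cluster_size, 3)))
    small = np.vstack(blobs) if blobs else np.empty((0, 3))

    points = np.vstack([surface, outliers, small])
    labels = np.concatenate([
        np.full(n_floor, "floor"),
        np.full(n_torso, "pig_torso"),
        np.full(n_head, "pig_head"),
        np.full(len(tail), "pig_tail"),
        np.full(len(outliers), "outlier_large"),
        np.full(len(small), "outlier_small"),
    ])
    cloud = PointCloud(points, labels)

    weight = allometric_weight(L, W, H, params, rng=rng)
    truth = SceneGroundTruth(
        true_weight=weight, body_length=L, body_width=W, body_height=H,
        label_counts=cloud.label_counts(),
    )
    return cloud, truth


def herd_seeds(n_pigs: int, seed: int) -> list[int]:
    """Deterministic per-pig child seeds spawned from a herd seed."""
    if n_pigs < 1:
        raise ParameterError("n_pigs must be >= 1")
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n_pigs) % (2 ** 31)]


def iter_herd(n_pigs: int, seed: int = 0,
              params_base: SceneParams | None = None):
    """Lazily yield ``n_pigs`` scenes; see :func:`generate_herd`."""
    base = params_base or SceneParams()
    base.validate()
    for s in herd_seeds(n_pigs, seed):
        yield generate_pig_scene(replace(base, seed=s))


def generate_herd(n_pigs: int, seed: int = 0,
                  params_base: SceneParams | None = None):
    """Generate ``n_pigs`` independent scenes with per-pig dimensions.

    Dimensions are drawn uniformly from the ranges in ``params_base``; each
    scene gets its own child seed spawned deterministically from ``seed``.
    """
    return list(iter_herd(n_pigs, seed, params_base))
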