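"""Alignment, outline extraction, sag profile and head/tail splitting."""

import numpy as np
import pytest

import pigback as pb
from pigback.errors import GeometryError, ParameterError
from pigback.segmentation import min_area_rectangle_angle


def grid_cloud(x0, x1, y0, y1, pitch, z=0.0):
    """Dense planar grid point cloud over a rectangle."""
    xs = np.arange(x0, x1 + pitch / 2, pitch)
    ys = np.arange(y0, y1 + pitch / 2, pitch)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel(),
                            np.full(gx.size, z)])


def rotate_z(points, deg):
    t = np.radians(deg)
    R = np.array([[np.cos(t), -np.sin(t), 0],
                  [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
    return points @ R.T


class TestProjectAlign:
    def test_project_drops_z(self):
        cloud = pb.PointCloud([[1, 2, 3]])
        np.testing.assert_array_equal(pb.project_xy(cloud), [[1, 2]])

    def test_axis_aligned_rectangle_needs_no_rotation(self):
        cloud = pb.PointCloud(grid_cloud(0, 2, 0, 1, 0.1))
        aligned, angle = pb.align_horizontal(cloud)
        assert abs(angle) < 1e-6 or abs(abs(angle) - 90) < 1e-6
        np.testing.assert_allclose(
            np.ptp(aligned.points[:, :2], axis=0), [2, 1], atol=1e-9)

    @pytest.mark.parametrize("deg", [30, -50, 75])
    def test_rotated_rectangle_recovers_area(self, deg):
        pts = rotate_z(grid_cloud(0, 2, 0, 1, 0.1), deg)
        aligned, angle = pb.align_horizontal(pb.PointCloud(pts))
        w, h = np.ptp(aligned.points[:, :2], axis=0)
        assert w * h == pytest.approx(2.0, abs=1e-9)
        assert w == pytest.approx(2.0, abs=1e-9)  # long side along x
        assert -90 < angle <= 90

    def test_alignment_is_isometric(self, rng):
        pts = rng.normal(size=(60, 3))
        cloud = pb.PointCloud(pts)
        aligned, _ = pb.align_horizontal(cloud)
        i, j = rng.integers(0, 60, 2), rng.integers(0, 60, 2)
        d0 = np.linalg.norm(pts[i] - pts[j], axis=1)
        d1 = np.linalg.norm(aligned.points[i] - aligned.points[j], axis=1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_min_rectangle_matches_dense_angle_scan(self, rng):
        pts2d = rng.normal(size=(80, 2))
        _, area = min_area_rectangle_angle(pts2d)
        # independent oracle: exhaustive scan over 20000 orientations
        best = np.inf
        for t in np.linspace(0, np.pi / 2, 20000):
            c, s = np.cos(t), np.sin(t)
            rx = pts2d[:, 0] * c - pts2d[:, 1] * s
            ry = pts2d[:, 0] * s + pts2d[:, 1] * c
            best = min(best, np.ptp(rx) * np.ptp(ry))
        assert area <= best + 1e-9
        assert area == pytest.approx(best, rel=1e-3)

    def test_collinear_projection_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(GeometryError):
            pb.align_horizontal(pb.PointCloud(pts))


class TestOutline:
    def test_dense_square_area(self):
        pts = grid_cloud(0, 1, 0, 1, 0.02)[:, :2]
        outline = pb.extract_outline(pts)
        assert outline.signed_area == pytest.approx(1.0, rel=0.02)

    def test_notched_square_concave_outline_vs_convex_hull(self):
        pts = grid_cloud(0, 1, 0, 1, 0.02)[:, :2]
        notch = (pts[:, 0] > 0.4) & (pts[:, 0] < 0.6) & (pts[:, 1] > 0.6)
        pts = pts[~notch]
        outline = pb.extract_outline(pts)
        hull = pb.convex_hull_2d(pts)
        hull_area = pb.Outline2D(hull.vertices).signed_area
        assert outline.signed_area == pytest.approx(1.0 - 0.2 * 0.4, rel=0.06)
        assert hull_area == pytest.approx(1.0, rel=0.02)

    def test_convex_disk_outline_close_to_hull(self, rng):
        pitch = 0.02
        pts = grid_cloud(-1, 1, -1, 1, pitch)[:, :2]
        pts = pts[np.linalg.norm(pts, axis=1) <= 1]
        outline = pb.extract_outline(pts)
        hull = pb.convex_hull_2d(outline.vertices)
        sag = pb.sag_depths(outline, hull)
        assert sag.depth.max() < 2 * pitch

    def test_too_small_alpha_suggests_larger(self):
        pts = np.vstack([grid_cloud(0, 1, 0, 1, 0.1)[:, :2],
                         grid_cloud(5, 6, 0, 1, 0.1)[:, :2]])
        with pytest.raises(GeometryError, match="alpha"):
            pb.extract_outline(pts, alpha=0.15)

    def test_needs_ten_points(self):
        with pytest.raises(ParameterError):
            pb.extract_outline(np.zeros((5, 2)))


class TestConvexHull2D:
    def test_square_plus_center(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        hull = pb.convex_hull_2d(pts)
        assert len(hull.vertices) == 4
        assert pb.Outline2D(hull.vertices).signed_area == pytest.approx(1.0)

    def test_triangle_area(self):
        hull = pb.convex_hull_2d(np.array([[0, 0], [1, 0], [0, 1.0]]))
        assert pb.Outline2D(hull.vertices).signed_area == pytest.approx(0.5)

    def test_matches_gift_wrapping_oracle(self, rng):
        def gift_wrap(pts):
            start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
            hull, cur = [start], start
            while True:
                nxt = (cur + 1) % len(pts)
                for cand in range(len(pts)):
                    if cand == cur:
                        continue
                    a = pts[nxt] - pts[cur]
                    b = pts[cand] - pts[cur]
                    cross = a[0] * b[1] - a[1] * b[0]
                    d_n = np.linalg.norm(pts[nxt] - pts[cur])
                    d_c = np.linalg.norm(pts[cand] - pts[cur])
                    if cross < -1e-12 or (abs(cross) < 1e-12 and d_c > d_n):
                        nxt = cand
                hull.append(nxt)
                cur = nxt
                if cur == start:
                    return set(hull)

        for _ in range(5):
            pts = rng.normal(size=(40, 2))
            hull = pb.convex_hull_2d(pts)
            assert set(hull.indices) == gift_wrap(pts)

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            pb.convex_hull_2d(np.column_stack([np.arange(5.0), np.arange(5.0)]))


class TestSagDepths:
    def test_convex_square_all_zero(self):
        outline = pb.Outline2D(np.array([[0, 0], [4, 0], [4, 4], [0, 4.0]]))
        hull = pb.convex_hull_2d(outline.vertices)
        assert pb.sag_depths(outline, hull).depth.max() == 0

    def test_notch_vertex_distance_to_hull_edge(self):
        outline = pb.Outline2D(
            np.array([[0, 0], [4, 0], [4, 4], [2, 2], [0, 4.0]]))
        hull = pb.convex_hull_2d(outline.vertices)
        sag = pb.sag_depths(outline, hull)
        assert sag.depth[3] == pytest.approx(2.0)  # to hull edge y = 4
        assert sag.depth[[0, 1, 2, 4]].max() == 0

    def test_similarity_scaling(self):
        verts = np.array([[0, 0], [4, 0], [4, 4], [2, 2], [0, 4.0]])
        hull1 = pb.convex_hull_2d(verts)
        s1 = pb.sag_depths(pb.Outline2D(verts), hull1)
        verts3 = verts * 3
        s3 = pb.sag_depths(pb.Outline2D(verts3), pb.convex_hull_2d(verts3))
        np.testing.assert_allclose(s3.depth, 3 * s1.depth)


class TestSplitHeadTail:
    def _notched_capsule(self, notch_head=0.7, notch_tail=-0.8, pitch=0.02):
        """Dense samples of a bar with V-notches at known x positions."""
        pts = grid_cloud(-1.5, 1.5, -0.5, 0.5, pitch)
        keep = np.ones(len(pts), dtype=bool)
        for xn, depth in ((notch_head, 0.5), (notch_tail, 0.45)):
            half = 0.15
            x, y = pts[:, 0], pts[:, 1]
            inside = (np.abs(x - xn) < half) & \
                (y > 0.5 - depth * (1 - np.abs(x - xn) / half))
            keep &= ~inside
        return pb.PointCloud(pts[keep])

    def test_cuts_land_on_the_notches(self):
        cloud = self._notched_capsule()
        res = pb.split_head_tail(cloud, sag_min=0.1)
        assert res.head_cut_x == pytest.approx(0.7, abs=0.06)
        assert res.tail_cut_x == pytest.approx(-0.8, abs=0.06)
        assert res.tail_cut_x < res.head_cut_x
        xs = res.cloud.points[:, 0]
        assert xs.min() > res.tail_cut_x and xs.max() < res.head_cut_x
        # trimmed extent strictly shorter than the input extent
        assert np.ptp(xs) < np.ptp(cloud.points[:, 0])

    def test_capsule_without_notches_left_uncut(self):
        cloud = pb.PointCloud(grid_cloud(-1.5, 1.5, -0.5, 0.5, 0.02))
        with pytest.warns(UserWarning):
            res = pb.split_head_tail(cloud, sag_min=0.05)
        assert len(res.warnings) == 2
        assert len(res.cloud) == len(cloud)

    def test_synthetic_pig_head_tail_removal(self, aligned_pig):
        res = pb.split_head_tail(aligned_pig)
        lab_in = aligned_pig.labels
        lab_out = res.cloud.labels
        ht_in = np.isin(lab_in, ("pig_head", "pig_tail")).sum()
        ht_out = np.isin(lab_out, ("pig_head", "pig_tail")).sum()
        torso_in = (lab_in == "pig_torso").sum()
        torso_out = (lab_out == "pig_torso").sum()
        assert 1 - ht_out / ht_in >= 0.80   # most of head+tail removed
        assert 1 - torso_out / torso_in <= 0.05  # torso kept

    def test_invalid_parameters(self, aligned_pig):
        with pytest.raises(ParameterError):
            pb.split_head_tail(aligned_pig, sag_min=0)
        with pytest.raises(ParameterError):
            pb.split_head_tail(aligned_pig, head_direction="up")
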