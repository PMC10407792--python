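import numpy as np
import pytest

from conftest import sunflower_disk
from soyphen.cloud import PointCloud
from soyphen.lpm import (
    LPMConfig,
    StageError,
    aabb_volume,
    extract_all,
    greedy_triangulate,
    heron_area,
    leaf_length_width,
    leaf_tilt,
    leaf_volume,
    plant_height,
    principal_axes_correction,
    project_to_xy,
    projection_extent,
)
from soyphen.synth import make_leaf


def ellipse_cloud(rng, L=6.0, W=4.0, n=2000, tilt_deg=0.0, noise=0.0):
    pts, _ = make_leaf(L, W, tilt_deg=tilt_deg, curvature=0.0,
                       density=n / (np.pi * L * W / 4), noise_sd=noise,
                       seed=int(rng.integers(2**31)))
    return PointCloud(pts)


class TestPlantHeight:
    def test_forced_arithmetic(self):
        pc = PointCloud([[0, 0, 0], [1, 1, 30.0]])
        assert plant_height(pc, 0.0) == 30.0

    def test_single_point(self):
        assert plant_height(PointCloud([[0, 0, 5.0]]), 0.0) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            plant_height(PointCloud(np.empty((0, 3))))


class TestPrincipalAxesCorrection:
    def test_axis_aligned_box_volume_unchanged(self):
        g = np.linspace(0, 1, 6)
        pts = np.array([[4 * x, 2 * y, z] for x in g for y in g for z in g])
        vol, _ = aabb_volume(PointCloud(pts), keep_z=True)
        assert abs(vol - 8.0) < 1e-9

    def test_rotated_box_volume_not_larger(self, rng):
        pts = rng.uniform(0, 1, (2000, 3)) * [4, 1, 1]
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rot = pts @ R.T
        vol_corr, _ = aabb_volume(PointCloud(rot), keep_z=True)
        lo, hi = rot.min(0), rot.max(0)
        assert vol_corr <= np.prod(hi - lo) + 1e-9

    def test_isotropic_sphere_volume_stable(self, rng):
        pts = rng.normal(size=(5000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        v1, _ = aabb_volume(PointCloud(pts), keep_z=False)
        v2, _ = aabb_volume(PointCloud(pts @ _random_rotation(rng).T), keep_z=False)
        assert abs(v1 - v2) / v1 < 0.01

    def test_returns_rotation(self, rng):
        pts = rng.uniform(0, 1, (100, 3))
        _, R = principal_axes_correction(PointCloud(pts), keep_z=False)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) > 0


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


class TestAabbVolume:
    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float
        )
        vol, got = aabb_volume(PointCloud(corners), keep_z=True)
        assert abs(vol - 1.0) < 1e-9
        assert got.shape == (8, 3)

    def test_dense_box(self, rng):
        pts = rng.uniform(0, 1, (20000, 3)) * [2, 3, 4]
        vol, _ = aabb_volume(PointCloud(pts), keep_z=True)
        assert abs(vol - 24.0) / 24.0 < 0.02

    def test_single_point_zero(self):
        vol, _ = aabb_volume(PointCloud([[1.0, 2, 3]]))
        assert vol == 0.0


class TestLeafLengthWidth:
    def test_flat_ellipse(self, rng):
        pc = ellipse_cloud(rng, L=6, W=4, n=3000)
        length, width, base, tip = leaf_length_width(pc)
        assert abs(length - 6) / 6 < 0.02
        assert abs(width - 4) / 4 < 0.02

    def test_collinear_leaf_zero_width(self):
        pc = PointCloud([[0, 0, 0], [1, 0, 0], [3.0, 0, 0]])
        length, width, base, tip = leaf_length_width(pc)
        assert length == 3.0
        assert width == 0.0

    def test_rotation_invariant_length(self, rng):
        pc = ellipse_cloud(rng, L=8, W=3, n=1500)
        R = _random_rotation(rng)
        l1, w1, *_ = leaf_length_width(pc)
        l2, w2, *_ = leaf_length_width(PointCloud(pc.points @ R.T))
        assert abs(l1 - l2) < 1e-6
        assert abs(w1 - w2) < 1e-6

    def test_width_never_exceeds_length(self, rng):
        for _ in range(5):
            pc = ellipse_cloud(rng, L=5, W=4.8, n=800, noise=0.05)
            length, width, *_ = leaf_length_width(pc)
            assert width <= length

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            leaf_length_width(PointCloud([[0, 0, 0], [1, 0, 0.0]]))


class TestLeafVolume:
    def test_single_point_one_cell(self):
        assert leaf_volume(PointCloud([[0.0, 0, 0]]), 0.5) == 0.125

    def test_solid_cube(self, rng):
        pts = rng.uniform(0, 1, (60000, 3))
        vol = leaf_volume(PointCloud(pts), 0.1)
        assert abs(vol - 1.0) < 0.05

    def test_scales_as_alpha_cubed(self, rng):
        pts = rng.uniform(0, 1, (3000, 3))
        alpha = 13.5
        v1 = leaf_volume(PointCloud(pts), 0.1)
        v2 = leaf_volume(PointCloud(pts * alpha), 0.1 * alpha)
        assert abs(v2 - alpha**3 * v1) / (alpha**3 * v1) < 1e-9

    def test_invalid_cell(self):
        with pytest.raises(ValueError):
            leaf_volume(PointCloud([[0.0, 0, 0]]), 0.0)


class TestProjection:
    def test_drops_z_preserves_order(self):
        pc = PointCloud([[1.0, 2, 3], [4, 5, 6]])
        out = project_to_xy(pc)
        np.testing.assert_array_equal(out, [[1, 2], [4, 5]])

    def test_vertical_leaf_projects_to_line(self, rng):
        pc = ellipse_cloud(rng, L=6, W=4, n=500, tilt_deg=90.0)
        proj = project_to_xy(pc)
        # footprint collapses: the second singular value vanishes
        c = proj - proj.mean(0)
        s = np.linalg.svd(c, compute_uv=False)
        assert s[1] < 1e-6 * s[0]


class TestHeronArea:
    def test_right_triangle(self):
        assert heron_area(3, 4, 5) == 6.0

    def test_degenerate_zero(self):
        assert heron_area(1, 1, 2) == 0.0

    def test_matches_shoelace_on_random_triangles(self, rng):
        for _ in range(1000):
            tri = rng.uniform(0, 10, (3, 2))
            a = np.linalg.norm(tri[1] - tri[2])
            b = np.linalg.norm(tri[0] - tri[2])
            c = np.linalg.norm(tri[0] - tri[1])
            shoelace = 0.5 * abs(
                (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
                - (tri[1, 1] - tri[0, 1]) * (tri[2, 0] - tri[0, 0])
            )
            assert abs(heron_area(a, b, c) - shoelace) < 1e-9

    def test_inequality_violation_rejected(self):
        with pytest.raises(ValueError):
            heron_area(1, 1, 5)


class TestGreedyTriangulate:
    def test_three_points_one_triangle(self):
        mesh = greedy_triangulate(np.array([[0, 0], [1, 0], [0, 1.0]]))
        assert mesh.n_triangles == 1
        assert abs(mesh.total_area - 0.5) < 1e-12

    def test_unit_square_two_triangles(self):
        mesh = greedy_triangulate(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        assert mesh.n_triangles == 2
        assert abs(mesh.total_area - 1.0) < 1e-12

    def test_disk_area(self):
        mesh = greedy_triangulate(sunflower_disk(2000))
        assert abs(mesh.total_area - np.pi) / np.pi < 0.02

    def test_heron_equals_shoelace_per_triangle(self, rng):
        pts = rng.uniform(0, 5, (300, 2))
        mesh = greedy_triangulate(pts)
        v = mesh.vertices
        t = mesh.triangles
        shoelace = 0.5 * np.abs(
            (v[t[:, 1], 0] - v[t[:, 0], 0]) * (v[t[:, 2], 1] - v[t[:, 0], 1])
            - (v[t[:, 1], 1] - v[t[:, 0], 1]) * (v[t[:, 2], 0] - v[t[:, 0], 0])
        )
        np.testing.assert_allclose(mesh.areas, shoelace, atol=1e-9)

    def test_no_overlap_total_bounded_by_hull(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.uniform(0, 3, (500, 2))
        mesh = greedy_triangulate(pts)
        hull = ConvexHull(pts)
        assert mesh.total_area <= hull.volume + 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            greedy_triangulate(np.array([[0, 0], [1, 0], [2, 0.0]]))


class TestProjectionExtent:
    def test_unit_square(self):
        l, w = projection_extent(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        assert abs(l - 1) < 1e-9 and abs(w - 1) < 1e-9

    def test_ellipse_extents(self, rng):
        pc = ellipse_cloud(rng, L=6, W=4, n=4000)
        l, w = projection_extent(project_to_xy(pc))
        assert abs(l - 6) / 6 < 0.02
        assert abs(w - 4) / 4 < 0.02

    def test_single_point(self):
        assert projection_extent(np.array([[2.0, 3.0]])) == (0.0, 0.0)

    def test_rotation_invariance(self, rng):
        pts = rng.uniform(0, 1, (200, 2)) * [5, 2]
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        l1, w1 = projection_extent(pts)
        l2, w2 = projection_extent(pts @ R.T)
        assert abs(l1 - l2) < 1e-9 and abs(w1 - w2) < 1e-9


class TestLeafTilt:
    def test_horizontal_leaf(self, rng):
        pc = ellipse_cloud(rng, n=500)
        info = leaf_tilt(pc, 0.5, seed=0)
        assert info.tilt_angle < 1e-6
        assert info.fit_rmse < 1e-9

    def test_45_degree_plane(self, rng):
        xy = rng.uniform(0, 4, (400, 2))
        pts = np.c_[xy[:, 0], xy[:, 1], xy[:, 0]]  # z = x
        info = leaf_tilt(PointCloud(pts), 0.5, seed=0)
        assert abs(info.tilt_angle - 45.0) < 1e-6

    def test_angle_always_in_range(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(50, 3)) @ _random_rotation(rng).T
            info = leaf_tilt(PointCloud(pts), 1.0, seed=0)
            assert 0.0 <= info.tilt_angle <= 90.0


class TestExtractAll:
    def test_empty_cloud_names_stage(self):
        with pytest.raises(StageError, match="input"):
            extract_all(PointCloud(np.empty((0, 3))))

    def test_deterministic(self, default_plant):
        from soyphen.pipeline import run_pipeline

        pc, _ = default_plant
        r1, _ = run_pipeline(pc)
        r2, _ = run_pipeline(pc)
        assert r1.plant_height_cm == r2.plant_height_cm
        for a, b in zip(r1.leaves, r2.leaves):
            assert a.length_cm == b.length_cm
            assert a.projection_area_cm2 == b.projection_area_cm2
            assert a.tilt.tilt_angle == b.tilt.tilt_angle

    def test_leaf_invariants_hold(self, default_plant):
        from soyphen.pipeline import run_pipeline

        pc, truth = default_plant
        rec, _ = run_pipeline(pc)
        assert rec.leaf_count == len(rec.leaves)
        assert rec.plant_height_cm > 0
        for leaf in rec.leaves:
            assert leaf.width_cm <= leaf.length_cm
            assert leaf.projection_length_cm <= leaf.length_cm
            assert (
                leaf.projection_area_cm2
                <= leaf.projection_length_cm * leaf.projection_width_cm
            )
            assert 0 <= leaf.tilt.tilt_angle <= 90
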