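import numpy as np
import pytest
from scipy.spatial.distance import squareform, pdist

from soyphen.cloud import PointCloud
from soyphen.segment import (
    euclidean_cluster,
    laplacian_smooth,
    ols_plane_fit,
    ransac_cylinder,
    split_stem_leaves,
)


def brute_epsilon_components(pts, tol):
    """Reference connected components of the epsilon-distance graph."""
    n = len(pts)
    adj = squareform(pdist(pts)) <= tol
    labels = -np.ones(n, dtype=int)
    lab = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = lab
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if labels[v] < 0:
                    labels[v] = lab
                    stack.append(v)
        lab += 1
    return labels


def cylinder_points(rng, radius, height, n, axis_noise=0.0):
    th = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, height, n)
    pts = np.stack([radius * np.cos(th), radius * np.sin(th), z], axis=1)
    if axis_noise:
        pts += rng.normal(0, axis_noise, pts.shape)
    return pts


class TestEuclideanCluster:
    def test_single_blob(self, rng):
        pts = rng.normal(0, 0.1, (100, 3))
        cs = euclidean_cluster(PointCloud(pts), tolerance=0.5)
        assert cs.n_clusters == 1 and len(cs.noise) == 0
        assert len(cs.clusters[0]) == 100

    def test_two_blobs_match_oracle(self, rng):
        a = rng.normal(0, 0.1, (100, 3))
        b = rng.normal(0, 0.1, (100, 3)) + [10, 0, 0]
        pts = np.vstack([a, b])
        tol = 1.0
        cs = euclidean_cluster(PointCloud(pts), tol)
        labels = brute_epsilon_components(pts, tol)
        assert cs.n_clusters == labels.max() + 1 == 2
        for members in cs.clusters:
            assert len(set(labels[members])) == 1

    def test_min_size_sends_to_noise(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]])
        cs = euclidean_cluster(PointCloud(pts), 1.0, min_cluster_size=5)
        assert cs.n_clusters == 0 and len(cs.noise) == 3

    def test_empty_cloud(self):
        cs = euclidean_cluster(PointCloud(np.empty((0, 3))), 1.0)
        assert cs.n_clusters == 0 and len(cs.noise) == 0

    def test_partition_property(self, rng):
        pts = rng.uniform(0, 4, (300, 3))
        cs = euclidean_cluster(PointCloud(pts), 0.4, min_cluster_size=3)
        all_idx = np.sort(np.concatenate(cs.clusters + [cs.noise]))
        np.testing.assert_array_equal(all_idx, np.arange(300))

    def test_exact_membership_vs_oracle(self, rng):
        pts = rng.uniform(0, 5, (1000, 3))
        tol = 0.45
        cs = euclidean_cluster(PointCloud(pts), tol, min_cluster_size=1)
        labels = brute_epsilon_components(pts, tol)
        assert cs.n_clusters == labels.max() + 1
        for members in cs.clusters:
            assert len(set(labels[members])) == 1


class TestRansacCylinder:
    def test_noiseless_cylinder_recovered(self, rng):
        pts = cylinder_points(rng, 0.3, 5.0, 500)
        model = ransac_cylinder(
            PointCloud(pts), dist_threshold=0.02, radius_bounds=(0.05, 1.0), seed=0
        )
        assert abs(model.radius - 0.3) / 0.3 < 0.01
        axis_angle = np.degrees(np.arccos(abs(model.axis_direction[2])))
        assert axis_angle < 1.0

    def test_cylinder_with_sphere_clutter(self, rng):
        cyl = cylinder_points(rng, 0.3, 5.0, 800, axis_noise=0.005)
        sph = rng.normal(size=(200, 3))
        sph = 2.0 * sph / np.linalg.norm(sph, axis=1, keepdims=True) + [3, 3, 2.5]
        pc = PointCloud(np.vstack([cyl, sph]))
        model = ransac_cylinder(
            pc, dist_threshold=0.03, radius_bounds=(0.05, 1.0), seed=0
        )
        recall = np.mean(np.isin(np.arange(800), model.inlier_indices))
        assert recall >= 0.95

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            ransac_cylinder(PointCloud(rng.normal(size=(5, 3))), 0.1)

    def test_radius_bounds_enforced(self, rng):
        pts = cylinder_points(rng, 0.3, 5.0, 400)
        model = ransac_cylinder(
            PointCloud(pts), 0.02, radius_bounds=(0.05, 1.0), seed=0
        )
        assert 0.05 <= model.radius <= 1.0


class TestSplitStemLeaves:
    def test_margin_zero_is_inlier_set(self, rng):
        pts = cylinder_points(rng, 0.3, 5.0, 400, axis_noise=0.01)
        pc = PointCloud(pts)
        model = ransac_cylinder(pc, 0.04, radius_bounds=(0.05, 1.0), seed=0)
        stem, leaves = split_stem_leaves(pc, model, margin=0.0, junction_sor=None)
        np.testing.assert_array_equal(
            stem.points, pts[model.inlier_indices]
        )

    def test_no_points_near_axis(self, rng):
        pts = cylinder_points(rng, 0.3, 5.0, 300)
        pc = PointCloud(pts)
        model = ransac_cylinder(pc, 0.02, radius_bounds=(0.05, 1.0), seed=0)
        far = PointCloud(pts + [50.0, 0, 0])
        stem, leaves = split_stem_leaves(far,
            type(model)(model.axis_point, model.axis_direction, model.radius,
                        np.empty(0, dtype=int), 0.0, model.dist_threshold),
            margin=0.5, junction_sor=None)
        assert len(stem) == 0 and len(leaves) == len(far)

    def test_stem_and_leaf_recall(self, rng):
        stem = cylinder_points(rng, 0.3, 20.0, 1500, axis_noise=0.02)
        leaf1 = np.c_[rng.uniform(2, 8, (600, 1)), rng.uniform(-2, 2, (600, 1)),
                      rng.uniform(9, 10, (600, 1))]
        leaf2 = np.c_[rng.uniform(-8, -2, (600, 1)), rng.uniform(-2, 2, (600, 1)),
                      rng.uniform(14, 15, (600, 1))]
        pts = np.vstack([stem, leaf1, leaf2])
        pc = PointCloud(pts)
        model = ransac_cylinder(
            pc, 0.06, radius_bounds=(0.1, 1.0), seed=0,
            axis_hint=np.array([0.0, 0, 1]), max_axis_angle_deg=20.0,
        )
        s, l = split_stem_leaves(pc, model, margin=0.3, junction_sor=None)
        stem_set = {tuple(p) for p in s.points}
        stem_recall = np.mean([tuple(p) in stem_set for p in stem])
        leaf_set = {tuple(p) for p in l.points}
        leaf_recall = np.mean([tuple(p) in leaf_set for p in np.vstack([leaf1, leaf2])])
        assert stem_recall >= 0.95
        assert leaf_recall >= 0.95


class TestOlsPlaneFit:
    def test_exact_plane(self, rng):
        pts = np.c_[rng.uniform(0, 1, (40, 2)), np.full(40, 2.0)]
        model = ols_plane_fit(PointCloud(pts))
        assert model.rmse < 1e-12
        assert abs(abs(model.normal[2]) - 1) < 1e-9

    def test_noisy_plane_normal(self, rng):
        pts = np.c_[rng.uniform(0, 10, (500, 2)), rng.normal(0, 0.05, 500)]
        model = ols_plane_fit(PointCloud(pts))
        assert np.degrees(np.arccos(abs(model.normal[2]))) < 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ols_plane_fit(PointCloud([[0, 0, 0], [1, 0, 0.0]]))
        with pytest.raises(ValueError):
            ols_plane_fit(PointCloud([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]))


class TestLaplacianSmooth:
    def test_zero_iterations_identity(self, random_cloud):
        out = laplacian_smooth(random_cloud, iterations=0)
        np.testing.assert_array_equal(out.points, random_cloud.points)

    def test_coincident_points_fixed(self):
        pts = np.zeros((5, 3))
        out = laplacian_smooth(PointCloud(pts), k=2, lam=1.0, iterations=3)
        np.testing.assert_array_equal(out.points, pts)

    def test_residual_rms_decreases(self, rng):
        pts = np.c_[rng.uniform(0, 10, (400, 2)), rng.normal(0, 0.1, 400)]
        pc = PointCloud(pts)
        rms_prev = np.sqrt(np.mean(pts[:, 2] ** 2))
        for it in range(1, 6):
            out = laplacian_smooth(pc, k=8, lam=0.5, iterations=it)
            rms = np.sqrt(np.mean(out.points[:, 2] ** 2))
            assert rms < rms_prev
            rms_prev = rms

    def test_centroid_preserved_on_symmetric_graph(self):
        # a regular ring with an even k has a symmetric (circulant)
        # neighbour graph: smoothing must not drift the centroid
        th = 2 * np.pi * np.arange(24) / 24
        ring = np.c_[np.cos(th), np.sin(th), np.zeros(24)] + [3.0, -1.0, 2.0]
        out = laplacian_smooth(PointCloud(ring), k=4, lam=0.5, iterations=4)
        np.testing.assert_allclose(
            out.points.mean(axis=0), ring.mean(axis=0), atol=1e-9
        )

    def test_count_unchanged(self, random_cloud):
        out = laplacian_smooth(random_cloud, k=6, lam=0.3, iterations=2)
        assert len(out) == len(random_cloud)
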