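"""MLS smoothing, ball-pivoting reconstruction and leaf-area measurement."""

import numpy as np
import pytest

from phenocloud import (
    BPAParams,
    MLSParams,
    PointCloud,
    bpa_reconstruct,
    generate_leaf,
    leaf_area_pipeline,
    mesh_area,
    mls_smooth,
    one_sided_cut,
)
from phenocloud.cloud import NotMetricError, TriangleMesh
from phenocloud.leaf import median_nn_distance
from conftest import random_rotation


def heron_area(mesh: TriangleMesh) -> float:
    """Independent total-area computation via Heron's formula per triangle."""
    total = 0.0
    v = mesh.vertices
    for i, j, k in mesh.faces:
        a = np.linalg.norm(v[j] - v[i])
        b = np.linalg.norm(v[k] - v[j])
        c = np.linalg.norm(v[i] - v[k])
        s = 0.5 * (a + b + c)
        total += np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
    return total


class TestMLS:
    def test_plane_is_fixed_point(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, 800), rng.uniform(0, 1, 800),
                               np.zeros(800)])
        smoothed = mls_smooth(PointCloud(pts))
        assert np.abs(smoothed.points - pts).max() < 1e-9

    def test_noisy_plane_flattens(self, rng):
        """2 mm noise drops below 0.5 mm RMS with a noise-matched radius."""
        n = 2120
        pts = np.column_stack([rng.uniform(0, 0.1, n), rng.uniform(0, 0.1, n),
                               np.zeros(n)])
        noisy = pts + rng.normal(0, 0.002, (n, 3))
        params = MLSParams(search_radius=10.0 * median_nn_distance(noisy))
        smoothed = mls_smooth(PointCloud(noisy), params)
        assert np.sqrt((smoothed.points[:, 2] ** 2).mean()) < 0.0005

    def test_isolated_point_flagged_and_unchanged(self):
        pts = np.array([[0, 0, 0], [0.001, 0, 0], [0, 0.001, 0],
                        [0.001, 0.001, 0], [0.0005, 0.0005, 0],
                        [0.0005, 0, 0], [0, 0.0005, 0],
                        [10.0, 10.0, 10.0]])
        smoothed, sparse = mls_smooth(
            PointCloud(pts), MLSParams(search_radius=0.01), return_info=True)
        assert sparse[-1]
        np.testing.assert_array_equal(smoothed.points[-1], pts[-1])

    def test_count_and_order_preserved(self, rng):
        pts = rng.uniform(size=(200, 3)) * [1, 1, 0.001]
        smoothed = mls_smooth(PointCloud(pts))
        assert smoothed.points.shape == pts.shape
        # order: smoothed point i stays near input point i
        assert np.linalg.norm(smoothed.points - pts, axis=1).max() < 0.05


class TestBPA:
    def test_three_points_one_triangle(self):
        mesh = bpa_reconstruct(
            PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 0]]), BPAParams(radii=(2.0,)))
        assert mesh.n_faces == 1
        assert mesh_area(mesh) == pytest.approx(0.5)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            bpa_reconstruct(PointCloud([[0, 0, 0], [1, 0, 0]]))

    def test_regular_grid_area(self):
        """50x50 unit-square grid meshes to within 3% of 1 m^2."""
        g = np.linspace(0, 1, 50)
        xx, yy = np.meshgrid(g, g)
        cloud = PointCloud(np.column_stack([xx.ravel(), yy.ravel(),
                                            np.zeros(2500)]))
        s = 1.0 / 49.0
        mesh = bpa_reconstruct(cloud, BPAParams(radii=(1.5 * s, 2.5 * s)))
        assert mesh_area(mesh) == pytest.approx(1.0, rel=0.03)
        assert np.unique(mesh.faces).size / 2500 > 0.99

    def test_vertices_are_subset_of_input(self, rng):
        pts = np.column_stack([rng.uniform(0, 0.05, 500), rng.uniform(0, 0.05, 500),
                               np.zeros(500)])
        mesh = bpa_reconstruct(PointCloud(pts))
        np.testing.assert_array_equal(mesh.vertices, pts)

    def test_no_duplicate_triangles(self, rng):
        pts = np.column_stack([rng.uniform(0, 0.05, 400), rng.uniform(0, 0.05, 400),
                               np.zeros(400)])
        mesh = bpa_reconstruct(PointCloud(pts))
        keys = {frozenset(f) for f in mesh.faces.tolist()}
        assert len(keys) == mesh.n_faces

    def test_radii_validation(self):
        with pytest.raises(ValueError, match="ascending"):
            BPAParams(radii=(0.002, 0.001))


class TestMeshArea:
    def test_unit_square_two_triangles(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                            [[0, 1, 2], [0, 2, 3]])
        assert mesh_area(mesh) == pytest.approx(1.0)

    def test_degenerate_triangle_contributes_zero(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        assert mesh_area(mesh) == 0.0

    def test_similarity_scaling_law(self, rng):
        verts = rng.normal(size=(20, 3))
        faces = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
        a1 = mesh_area(TriangleMesh(verts, faces))
        a2 = mesh_area(TriangleMesh(3.0 * verts, faces))
        assert a2 == pytest.approx(9.0 * a1, rel=1e-12)

    def test_matches_heron_oracle(self, rng):
        pts = np.column_stack([rng.uniform(0, 0.05, 600), rng.uniform(0, 0.05, 600),
                               np.zeros(600)])
        mesh = bpa_reconstruct(PointCloud(pts))
        assert mesh_area(mesh) == pytest.approx(heron_area(mesh), rel=1e-12)


class TestLeafAreaPipeline:
    def test_half_cylinder_within_five_percent(self):
        fix = generate_leaf("half-cylinder", seed=3)
        result = leaf_area_pipeline(fix.cloud)
        assert result.area == pytest.approx(fix.truth["leaf_area"], rel=0.05)
        assert result.diagnostics["vertex_usage"] > 0.9

    def test_flat_disc_within_five_percent(self):
        fix = generate_leaf("flat-disc", seed=3)
        result = leaf_area_pipeline(fix.cloud)
        assert result.area == pytest.approx(np.pi * 0.0025, rel=0.05)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            leaf_area_pipeline(PointCloud(np.empty((0, 3)), is_metric=True))

    def test_non_metric_cloud_refused(self):
        fix = generate_leaf("flat-disc", seed=0)
        bare = PointCloud(fix.cloud.points, is_metric=False)
        with pytest.raises(NotMetricError):
            leaf_area_pipeline(bare)

    def test_area_invariant_under_rigid_motion(self):
        fix = generate_leaf("half-cylinder", seed=1)
        r1 = leaf_area_pipeline(fix.cloud)
        R = random_rotation(9)
        moved = PointCloud(fix.cloud.points @ R.T + np.array([1.0, -2.0, 0.5]),
                           is_metric=True)
        r2 = leaf_area_pipeline(moved)
        assert r2.area == pytest.approx(r1.area, rel=1e-6)

    def test_one_sided_capture_biases_area_low(self):
        """A curled blade captured from one side loses its far surface."""
        fix = generate_leaf("s-curl", seed=0)
        cut = one_sided_cut(fix, view_direction=(0, 0, 1))
        partial = leaf_area_pipeline(cut.cloud)
        assert partial.area < 0.8 * fix.truth["leaf_area"]
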