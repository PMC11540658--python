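"""Ellipsoid fitting and fruit volume estimation."""

import numpy as np
import pytest

from phenocloud import (
    PointCloud,
    align_to_principal_frame,
    fit_ellipsoid,
    fruit_volume_pipeline,
    generate_fruit,
)
from phenocloud.cloud import NotMetricError
from phenocloud.fruit import (
    coverage_fraction,
    ellipsoid_objective,
    fit_ellipsoid_pose,
)
from conftest import random_rotation


def grid_search_semi_axes(points, lo=0.005, hi=0.08, n=40, stages=2):
    """Two-stage exhaustive grid minimization of the algebraic objective."""
    lo = np.full(3, lo)
    hi = np.full(3, hi)
    sq = points**2
    best = None
    step = None
    for _ in range(stages):
        axes_grids = [np.linspace(lo[d], hi[d], n) for d in range(3)]
        mesh = np.meshgrid(*axes_grids, indexing="ij")
        inv = np.stack([1.0 / (m.ravel() ** 2) for m in mesh])
        f = (((sq @ inv) - 1.0) ** 2).sum(axis=0)
        i = int(np.argmin(f))
        best = np.array([m.ravel()[i] for m in mesh])
        step = np.array([g[1] - g[0] for g in axes_grids])
        lo, hi = best - step, best + step
    return best, step


def mc_volume(fit, n_samples=100_000, seed=0):
    """Monte-Carlo inside-ellipsoid volume from bounding-box sampling."""
    rng = np.random.default_rng(seed)
    axes = np.asarray(fit.semi_axes)
    box = 2.0 * axes
    samples = rng.uniform(-axes, axes, (n_samples, 3))
    inside = ((samples / axes) ** 2).sum(axis=1) <= 1.0
    return float(inside.mean() * np.prod(box))


class TestAlign:
    def test_centered_axis_aligned_samples(self):
        fix = generate_fruit((0.04, 0.03, 0.02), noise_sigma=0.0, seed=0)
        aligned, center, R = align_to_principal_frame(fix.cloud)
        assert np.abs(center).max() < 1e-3
        # orientation equals identity up to signed axis permutation
        assert np.allclose(np.abs(R), np.eye(3), atol=0.05)

    def test_translation_recovered(self):
        fix = generate_fruit((0.04, 0.03, 0.02), noise_sigma=0.0, seed=0)
        shifted = PointCloud(fix.cloud.points + np.array([1.0, 2.0, 3.0]),
                             is_metric=True)
        _, center, _ = align_to_principal_frame(shifted)
        base_center = fix.cloud.points.mean(axis=0)
        np.testing.assert_allclose(center, base_center + [1, 2, 3], atol=1e-9)

    def test_known_rotation_recovered_as_subspaces(self):
        fix = generate_fruit((0.05, 0.03, 0.02), noise_sigma=0.0, seed=1)
        R = random_rotation(2)
        rotated = PointCloud(fix.cloud.points @ R.T, is_metric=True)
        _, _, R_est = align_to_principal_frame(rotated)
        # columns of R_est must match columns of R up to sign
        dots = np.abs(R_est.T @ R)
        assert np.allclose(dots.max(axis=1), 1.0, atol=1e-3)

    def test_coplanar_cloud_rejected(self, rng):
        flat = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(ValueError, match="coplanar"):
            align_to_principal_frame(PointCloud(flat))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 10"):
            align_to_principal_frame(PointCloud(np.eye(3)))


class TestFitEllipsoid:
    def test_unit_sphere_identity(self):
        fix = generate_fruit((1.0, 1.0, 1.0), noise_sigma=0.0, n_points=500, seed=0)
        fit = fit_ellipsoid(fix.cloud)
        np.testing.assert_allclose(fit.semi_axes, (1.0, 1.0, 1.0), atol=1e-6)
        assert fit.residual < 1e-10
        assert fit.volume == pytest.approx(4.0 * np.pi / 3.0, rel=1e-6)

    def test_exact_ellipsoid_recovery(self):
        fix = generate_fruit((0.040, 0.030, 0.030), noise_sigma=0.0, seed=1)
        fit = fit_ellipsoid(fix.cloud)
        np.testing.assert_allclose(sorted(fit.semi_axes, reverse=True),
                                   (0.040, 0.030, 0.030), atol=1e-5)
        truth = 4.0 / 3.0 * np.pi * 0.040 * 0.030 * 0.030
        assert fit.volume == pytest.approx(truth, rel=1e-3)

    def test_matches_grid_search_oracle(self):
        fix = generate_fruit((0.04, 0.03, 0.03), noise_sigma=0.0005,
                             n_points=200, seed=3)
        aligned, _, _ = align_to_principal_frame(fix.cloud)
        fit = fit_ellipsoid(aligned)
        best, step = grid_search_semi_axes(aligned.points)
        assert np.all(np.abs(np.asarray(fit.semi_axes) - best) <= step)

    def test_front_hemisphere_within_ten_percent(self):
        """Half-space occlusion still recovers volume to 10%."""
        fix = generate_fruit((0.040, 0.030, 0.030), coverage_fraction=0.5,
                             noise_sigma=0.0005, seed=4)
        _, volume_cm3 = fruit_volume_pipeline(fix.cloud)
        truth = fix.truth["fruit_volume"] * 1e6
        assert volume_cm3 == pytest.approx(truth, rel=0.10)

    def test_volume_field_consistency(self):
        fix = generate_fruit(seed=5)
        fit = fit_ellipsoid(fix.cloud)
        a, b, c = fit.semi_axes
        assert fit.volume == pytest.approx(4.0 / 3.0 * np.pi * a * b * c, rel=1e-15)
        assert fit.residual == pytest.approx(
            ellipsoid_objective(fit.semi_axes, fix.cloud.points), rel=1e-12)


class TestPipeline:
    def test_sphere_volume_in_cm3(self):
        """A 3 cm-radius sphere reports (4/3) pi 27 = 113.10 cm^3."""
        fix = generate_fruit((0.03, 0.03, 0.03), noise_sigma=0.0, seed=0)
        _, volume_cm3 = fruit_volume_pipeline(fix.cloud)
        assert volume_cm3 == pytest.approx(113.097, rel=1e-3)

    def test_sixty_percent_coverage_within_fifteen_percent(self):
        fix = generate_fruit((0.04, 0.03, 0.03), coverage_fraction=0.6, seed=6)
        _, volume_cm3 = fruit_volume_pipeline(fix.cloud)
        truth = fix.truth["fruit_volume"] * 1e6
        assert volume_cm3 == pytest.approx(truth, rel=0.15)

    def test_five_point_cloud_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fruit_volume_pipeline(PointCloud(np.random.default_rng(0)
                                             .normal(size=(5, 3)), is_metric=True))

    def test_non_metric_refused(self):
        fix = generate_fruit(seed=0)
        with pytest.raises(NotMetricError):
            fruit_volume_pipeline(PointCloud(fix.cloud.points))

    def test_monte_carlo_volume_consistency(self):
        fix = generate_fruit(seed=7)
        fit, _ = fruit_volume_pipeline(fix.cloud)
        assert fit.volume == pytest.approx(mc_volume(fit), rel=0.01)

    def test_rigid_motion_invariance(self):
        fix = generate_fruit((0.04, 0.03, 0.03), coverage_fraction=0.7, seed=8)
        _, v1 = fruit_volume_pipeline(fix.cloud)
        R = random_rotation(4)
        moved = PointCloud(fix.cloud.points @ R.T + np.array([0.5, 1.0, -0.3]),
                           is_metric=True)
        _, v2 = fruit_volume_pipeline(moved)
        assert v2 == pytest.approx(v1, rel=1e-6)

    def test_pose_refined_fit_reports_proper_rotation(self):
        fix = generate_fruit((0.04, 0.03, 0.03), coverage_fraction=0.75, seed=9)
        aligned, _, _ = align_to_principal_frame(fix.cloud)
        fit = fit_ellipsoid_pose(aligned)
        R = fit.orientation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_coverage_diagnostic_tracks_occlusion(self):
        full = generate_fruit(coverage_fraction=1.0, seed=10)
        half = generate_fruit(coverage_fraction=0.5, seed=10)
        fit_full, _ = fruit_volume_pipeline(full.cloud)
        fit_half, _ = fruit_volume_pipeline(half.cloud)
        assert fit_full.coverage > 0.9
        assert fit_half.coverage < 0.75


def test_coverage_fraction_full_sphere(rng):
    d = rng.standard_normal((5000, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    assert coverage_fraction(d, np.zeros(3)) > 0.95
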