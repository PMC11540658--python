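"""Fruit volume estimation by least-squares ellipsoid fitting.

A limited-angle capture sees only the camera-facing cap of a fruit, so
its volume is extrapolated by fitting an axis-aligned ellipsoid to the
observed points under an assumed symmetry.  The cloud is first posed by
centroid + principal axes (the objective below carries no pose terms),
then the semi-axes (a, b, c) minimize

    f(a, b, c) = sum_i (x_i^2/a^2 + y_i^2/b^2 + z_i^2/c^2 - 1)^2

over the M aligned points — the algebraic squared distance of each point
from the ellipsoid surface.  The optimization runs in log(a), log(b),
log(c) so positivity needs no constraints, with an analytic Jacobian.
The reported volume is V = (4/3) pi a b c.

Under partial coverage the centroid is pulled toward the observed cap
and the cap's covariance eigenvectors stop tracking the fruit's axes, so
the full pipeline refines the pose (center and orientation) within the
same least-squares problem, initialized at the centroid/PCA estimate
(:func:`fit_ellipsoid_pose`).  The pure three-parameter objective stays
available as :func:`fit_ellipsoid` — it is the form whose optimum a grid
search can certify.  The coverage-fraction diagnostic lets callers
filter fits made from thin observed caps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cloud import PointCloud

__all__ = [
    "EllipsoidFit",
    "align_to_principal_frame",
    "fit_ellipsoid",
    "fit_ellipsoid_pose",
    "fruit_volume_pipeline",
    "ellipsoid_objective",
    "coverage_fraction",
    "ellipsoid_mesh",
]

_MIN_POINTS = 10


def ellipsoid_objective(semi_axes, points: np.ndarray) -> float:
    """The fitted objective f(a,b,c): sum of squared algebraic residuals."""
    a, b, c = semi_axes
    q = (points[:, 0] / a) ** 2 + (points[:, 1] / b) ** 2 + (points[:, 2] / c) ** 2
    return float(np.sum((q - 1.0) ** 2))


@dataclass
class EllipsoidFit:
    """Fitted ellipsoid: pose, semi-axes, objective value and volume."""

    center: np.ndarray          # (3,) meters, world frame
    orientation: np.ndarray     # (3,3) rotation, fit frame -> world frame
    semi_axes: tuple            # (a, b, c) meters
    residual: float             # objective value at the optimum
    n_points: int
    coverage: float = 1.0       # solid-angle fraction seen from the center

    def __post_init__(self):
        a, b, c = self.semi_axes
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or np.linalg.det(R) < 0:
            raise ValueError("orientation must be a proper rotation matrix")
        self.orientation = R
        self.center = np.asarray(self.center, dtype=float)

    @property
    def volume(self) -> float:
        """Cubic meters: (4/3) pi a b c."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def volume_cm3(self) -> float:
        return self.volume * 1e6


def align_to_principal_frame(cloud: PointCloud):
    """Center a cloud at its centroid and rotate into its principal axes.

    Axes are ordered by descending variance and the frame is forced
    right-handed.  Returns (aligned cloud, center, orientation) with
    ``orientation`` mapping fit frame -> world frame."""
    pts = cloud.points
    if pts.shape[0] < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points, got {pts.shape[0]}")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * max(evals[0], 1e-300):
        raise ValueError("degenerate covariance: points are (near-)coplanar")
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    aligned = centered @ evecs
    return cloud.with_points(aligned), center, evecs


def fit_ellipsoid(aligned: PointCloud, init=None) -> EllipsoidFit:
    """Minimize the algebraic ellipsoid objective over positive semi-axes.

    ``aligned`` must already be centered and axis-aligned (see
    :func:`align_to_principal_frame`).  ``init`` seeds (a, b, c); the
    default is each axis's max absolute coordinate."""
    pts = aligned.points
    if pts.shape[0] < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points, got {pts.shape[0]}")
    if init is None:
        init = np.abs(pts).max(axis=0)
    init = np.asarray(init, dtype=float)
    if np.any(init <= 0):
        raise ValueError("initial semi-axes must be positive")

    sq = pts**2

    def residuals(u):
        return sq @ np.exp(-2.0 * u) - 1.0

    def jacobian(u):
        return -2.0 * sq * np.exp(-2.0 * u)

    result = least_squares(
        residuals, np.log(init), jac=jacobian,
        method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=500 * 3)
    if not np.all(np.isfinite(result.x)) or not np.isfinite(result.cost):
        raise RuntimeError(
            f"ellipsoid fit failed: non-finite iterate (status {result.status}, "
            f"{result.message}); last iterate {result.x}")
    axes = tuple(np.exp(result.x))
    return EllipsoidFit(
        center=np.zeros(3), orientation=np.eye(3), semi_axes=axes,
        residual=ellipsoid_objective(axes, pts), n_points=pts.shape[0],
    )


def fit_ellipsoid_pose(aligned: PointCloud) -> EllipsoidFit:
    """Least-squares ellipsoid with center and orientation refined jointly.

    The three-parameter objective assumes the cloud is centered on the
    fruit and aligned with its axes; with a partially observed fruit both
    assumptions fail (the centroid sits inside the observed cap, and the
    cap's covariance eigenvectors are nearly degenerate).  Here the same
    algebraic residual is minimized over semi-axes, center and a rotation
    (rotation-vector parametrization), starting from the centroid/PCA
    pose of ``aligned``.  Returns the fit in the frame of ``aligned``:
    ``center`` and ``orientation`` are the refinement offsets."""
    from scipy.spatial.transform import Rotation

    pts = aligned.points
    if pts.shape[0] < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points, got {pts.shape[0]}")
    init = np.abs(pts).max(axis=0)
    if np.any(init <= 0):
        raise ValueError("degenerate cloud: zero extent along an axis")

    def residuals(p):
        rot = Rotation.from_rotvec(p[6:]).as_matrix()
        d = (pts - p[3:6]) @ rot
        return (d * d) @ np.exp(-2.0 * p[:3]) - 1.0

    p0 = np.concatenate([np.log(init), np.zeros(6)])
    result = least_squares(
        residuals, p0, method="lm", xtol=1e-13, ftol=1e-13, gtol=1e-13,
        max_nfev=500 * 9)
    if not np.all(np.isfinite(result.x)):
        raise RuntimeError(
            f"ellipsoid pose fit failed (status {result.status}, "
            f"{result.message}); last iterate {result.x}")
    axes = tuple(np.exp(result.x[:3]))
    center = result.x[3:6]
    rot = Rotation.from_rotvec(result.x[6:]).as_matrix()
    final = (pts - center) @ rot
    # row-vector convention: x_fit = x_aligned @ rot, so the matrix `rot`
    # maps fit-frame coordinates back to the aligned frame
    return EllipsoidFit(
        center=center, orientation=rot, semi_axes=axes,
        residual=ellipsoid_objective(axes, final), n_points=pts.shape[0],
    )


def coverage_fraction(points: np.ndarray, center: np.ndarray, n_bins: int = 256) -> float:
    """Fraction of the view sphere covered by point directions from ``center``.

    Directions are binned against a Fibonacci lattice; the occupied
    fraction approximates the solid-angle coverage and flags fits made
    from thin observed caps."""
    d = points - center
    norms = np.linalg.norm(d, axis=1)
    d = d[norms > 0] / norms[norms > 0, None]
    i = np.arange(n_bins)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n_bins
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * i / golden
    lattice = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    nearest = np.argmax(d @ lattice.T, axis=1)
    return float(np.unique(nearest).size) / n_bins


def fruit_volume_pipeline(cloud: PointCloud):
    """Pose, fit and report a fruit's ellipsoid volume.

    Centroid/PCA give the initial pose; the fit then refines center and
    orientation together with the semi-axes (partial coverage biases the
    initial pose; see :func:`fit_ellipsoid_pose`).  Returns
    (EllipsoidFit in world pose, volume in cm^3)."""
    cloud.require_metric("fruit_volume_pipeline")
    aligned, center, orientation = align_to_principal_frame(cloud)
    fit = fit_ellipsoid_pose(aligned)
    world_center = center + orientation @ fit.center
    world_orient = orientation @ fit.orientation
    full = EllipsoidFit(
        center=world_center, orientation=world_orient, semi_axes=fit.semi_axes,
        residual=fit.residual, n_points=fit.n_points,
        coverage=coverage_fraction(cloud.points, world_center),
    )
    return full, full.volume_cm3


def ellipsoid_mesh(fit: EllipsoidFit, subdivisions: int = 3):
    """Triangulated fitted ellipsoid (world frame) for visual QC export."""
    import trimesh

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = sphere.vertices * np.asarray(fit.semi_axes)
    verts = verts @ fit.orientation.T + fit.center
    from .cloud import TriangleMesh

    return TriangleMesh(verts, np.asarray(sphere.faces))
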