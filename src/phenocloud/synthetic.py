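"""Seeded generators of plant-organ point clouds with analytic ground truth.

Every fixture emulates what a forward-facing neural-radiance-field
capture exports: points sampled on organ surfaces, dense on the
camera-facing side and sparse or absent behind (controlled by an angular
coverage fraction over surface normals), with isotropic Gaussian surface
noise.  Ground-truth traits (node spacings, leaf area, fruit volume) are
computed in closed form from the generator parameters — never measured
from the generated cloud — so recovery tests compare against exact
values.

Randomness comes from numpy's PCG64 generator keyed by the fixture seed;
sub-organ streams are derived through ``SeedSequence([seed, offset])``
with fixed offsets, so identical (seed, parameters) reproduce the cloud
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import DEFAULT_MARKER_EDGE_M, MarkerObservation
from .cloud import PointCloud

__all__ = [
    "PlantFixture",
    "generate_stem",
    "generate_leaf",
    "generate_fruit",
    "generate_marker",
    "one_sided_cut",
]

_GENERATOR = "numpy.PCG64"  # pinned for cross-platform reproducibility


@dataclass
class PlantFixture:
    """A synthetic organ cloud plus the exact traits it was built from."""

    cloud: PointCloud
    truth: dict
    seed: int
    capture: dict
    normals: np.ndarray | None = field(default=None, repr=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, stream])))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _sample_cylinder(rng, axis_start, axis_dir, length, radius, n):
    """Area-uniform sample of an open cylinder wall, with outward normals."""
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis_dir[2]) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, axis_dir)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    t = rng.uniform(0.0, length, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    normals = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    points = axis_start + np.outer(t, axis_dir) + radius * normals
    return points, normals


def generate_stem(
    node_spacings,
    stem_radius: float = 0.006,
    branch_length: float = 0.08,
    density: float = 80000.0,
    noise_sigma: float = 0.002,
    seed: int = 0,
    *,
    branch_radius: float | None = None,
    margin: float = 0.08,
    branch_elevation_deg: float = 40.0,
) -> PlantFixture:
    """Vertical stem tube with one lateral branch tube per node.

    Nodes sit on the stem axis at cumulative heights given by
    ``node_spacings`` (meters between consecutive nodes); branches leave
    at phyllotactic azimuths.  Truth inter-node distances are exactly the
    input spacings.
    """
    spacings = np.asarray(node_spacings, dtype=float)
    if spacings.size == 0 or np.any(spacings <= 0):
        raise ValueError("node_spacings must be positive")
    if stem_radius <= 0 or branch_length <= 0 or density <= 0:
        raise ValueError("stem_radius, branch_length and density must be positive")
    if branch_radius is None:
        branch_radius = 0.6 * stem_radius

    node_heights = margin + np.concatenate([[0.0], np.cumsum(spacings)])
    total_height = node_heights[-1] + margin
    rng = _rng(seed, 0)

    parts, normal_parts = [], []
    n_stem = max(500, int(round(density * 2.0 * np.pi * stem_radius * total_height)))
    pts, nrm = _sample_cylinder(
        rng, np.zeros(3), np.array([0.0, 0.0, 1.0]), total_height, stem_radius, n_stem)
    parts.append(pts)
    normal_parts.append(nrm)

    elev = np.deg2rad(branch_elevation_deg)
    for i, h in enumerate(node_heights):
        azim = np.deg2rad(137.5 * i)  # phyllotactic spiral
        direction = np.array([
            np.cos(elev) * np.cos(azim),
            np.cos(elev) * np.sin(azim),
            np.sin(elev)])
        start = np.array([0.0, 0.0, h])
        n_branch = max(200, int(round(
            density * 2.0 * np.pi * branch_radius * branch_length)))
        pts, nrm = _sample_cylinder(
            _rng(seed, 10 + i), start, direction, branch_length, branch_radius, n_branch)
        parts.append(pts)
        normal_parts.append(nrm)

    points = np.vstack(parts)
    normals = np.vstack(normal_parts)
    points = points + _rng(seed, 1).normal(0.0, noise_sigma, points.shape)

    node_positions = np.column_stack([
        np.zeros_like(node_heights), np.zeros_like(node_heights), node_heights])
    truth = {
        "node_positions": node_positions,
        "internode_distances": spacings.copy(),
    }
    capture = {
        "generator": _GENERATOR, "noise_sigma": noise_sigma,
        "density": density, "coverage": 1.0, "view_direction": None,
    }
    return PlantFixture(PointCloud(points, is_metric=True), truth, seed, capture, normals)


def _scurl_curve(arc_radius: float, sweep: float):
    """S-shaped generating curve of two opposite circular arcs.

    Returns (total length, position fn, normal fn) with the curve in the
    x-z plane, parametrized by arc length; closed-form length 2*R*sweep."""
    R, phi = arc_radius, sweep
    L = 2.0 * R * phi

    def pos(s):
        s = np.asarray(s, dtype=float)
        t = s / R
        x = np.where(t <= phi, R * np.sin(t),
                     R * np.sin(phi) + R * (np.sin(phi) - np.sin(2 * phi - t)))
        z = np.where(t <= phi, R * (1.0 - np.cos(t)),
                     R * (1.0 - np.cos(phi)) + R * (np.cos(2 * phi - t) - np.cos(phi)))
        return np.column_stack([x, z])

    def normal(s):
        s = np.asarray(s, dtype=float)
        t = s / R
        # unit normal (left of travel) flips with curvature sign at the join
        nx = np.where(t <= phi, -np.sin(t), np.sin(2 * phi - t))
        nz = np.where(t <= phi, np.cos(t), -np.cos(2 * phi - t))
        return np.column_stack([nx, nz])

    return L, pos, normal


def generate_leaf(
    shape: str = "flat-disc",
    *,
    radius: float = 0.05,
    height: float = 0.12,
    width: float = 0.06,
    arc_radius: float = 0.03,
    sweep: float = 2.0,
    density: float = 212000.0,
    noise_sigma: float = 0.0005,
    seed: int = 0,
) -> PlantFixture:
    """Parametric leaf surface sampled uniformly by area.

    Shapes: ``flat-disc`` (area pi r^2), ``half-cylinder`` (area pi r h,
    axis along z), ``s-curl`` (two opposite circular arcs of radius
    ``arc_radius`` swept ``sweep`` radians each, extruded ``width`` along
    y; area 2 * arc_radius * sweep * width).
    """
    rng = _rng(seed, 0)
    if shape == "flat-disc":
        if radius <= 0:
            raise ValueError("radius must be positive")
        area = np.pi * radius**2
        n = max(200, int(round(density * area)))
        r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
        th = rng.uniform(0.0, 2.0 * np.pi, n)
        points = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
        normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif shape == "half-cylinder":
        if radius <= 0 or height <= 0:
            raise ValueError("radius and height must be positive")
        area = np.pi * radius * height
        n = max(200, int(round(density * area)))
        th = rng.uniform(0.0, np.pi, n)       # area-uniform: |J| = r constant
        z = rng.uniform(0.0, height, n)
        points = np.column_stack([radius * np.cos(th), radius * np.sin(th), z])
        normals = np.column_stack([np.cos(th), np.sin(th), np.zeros(n)])
    elif shape == "s-curl":
        if arc_radius <= 0 or sweep <= 0 or width <= 0:
            raise ValueError("arc_radius, sweep and width must be positive")
        L, pos, nrm = _scurl_curve(arc_radius, sweep)
        area = L * width
        n = max(200, int(round(density * area)))
        s = rng.uniform(0.0, L, n)            # arc-length param: area-uniform
        y = rng.uniform(0.0, width, n)
        xz = pos(s)
        points = np.column_stack([xz[:, 0], y, xz[:, 1]])
        nxz = nrm(s)
        normals = np.column_stack([nxz[:, 0], np.zeros(n), nxz[:, 1]])
    else:
        raise ValueError(f"unknown leaf shape {shape!r}")

    points = points + _rng(seed, 1).normal(0.0, noise_sigma, points.shape)
    truth = {"leaf_area": float(area)}
    capture = {
        "generator": _GENERATOR, "noise_sigma": noise_sigma,
        "density": density, "coverage": 1.0, "view_direction": None,
        "shape": shape,
    }
    return PlantFixture(PointCloud(points, is_metric=True), truth, seed, capture, normals)


def generate_fruit(
    semi_axes=(0.04, 0.03, 0.03),
    coverage_fraction: float = 1.0,
    view_direction=(1.0, 0.0, 0.0),
    density: float = 150000.0,
    noise_sigma: float = 0.0005,
    seed: int = 0,
    *,
    n_points: int | None = None,
) -> PlantFixture:
    """Ellipsoid surface sampled uniformly by area, with an occlusion cap.

    Points are kept when their outward normal lies within the spherical
    cap of solid-angle fraction ``coverage_fraction`` around
    ``view_direction`` (the direction from fruit to camera) — the
    one-sided cloud a limited-angle capture produces.  Truth volume is
    (4/3) pi a b c.
    """
    a, b, c = (float(v) for v in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    view = np.asarray(view_direction, dtype=float)
    if not np.linalg.norm(view) > 0:
        raise ValueError("view_direction must be nonzero")
    view = view / np.linalg.norm(view)

    # Thomsen approximation is good enough for choosing a sample count
    p = 1.6075
    approx_area = 4.0 * np.pi * (
        ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    if n_points is None:
        n_points = max(300, int(round(density * approx_area)))

    rng = _rng(seed, 0)
    points = np.empty((0, 3))
    normals = np.empty((0, 3))
    gmax = max(a * b, a * c, b * c)
    while points.shape[0] < n_points:
        m = max(4 * n_points, 1000)
        u = rng.standard_normal((m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # accept-reject so density is uniform per surface area, not per angle
        g = np.sqrt((u[:, 0] * b * c) ** 2 + (u[:, 1] * a * c) ** 2
                    + (u[:, 2] * a * b) ** 2)
        keep = rng.uniform(0.0, gmax, m) < g
        pts = u[keep] * np.array([a, b, c])
        nrm = pts / np.array([a * a, b * b, c * c])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        points = np.vstack([points, pts])
        normals = np.vstack([normals, nrm])
    points, normals = points[:n_points], normals[:n_points]

    cos_max = 1.0 - 2.0 * coverage_fraction  # cap of matching solid angle
    visible = normals @ view >= cos_max
    points, normals = points[visible], normals[visible]

    points = points + _rng(seed, 1).normal(0.0, noise_sigma, points.shape)
    truth = {
        "semi_axes": (a, b, c),
        "fruit_volume": float(4.0 / 3.0 * np.pi * a * b * c),
    }
    capture = {
        "generator": _GENERATOR, "noise_sigma": noise_sigma,
        "density": density, "coverage": coverage_fraction,
        "view_direction": tuple(view),
    }
    return PlantFixture(PointCloud(points, is_metric=True), truth, seed, capture, normals)


def generate_marker(
    scale: float = 5.0,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    corner_noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    edge_length_m: float = DEFAULT_MARKER_EDGE_M,
) -> MarkerObservation:
    """Square marker corners as a reconstruction would report them.

    ``scale`` is reconstruction units per meter, so the true scale factor
    the calibration should recover is ``1 / scale``.  ``rotation`` /
    ``translation`` default to a seeded random rigid motion."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = _rng(seed, 0)
    if rotation is None:
        rotation = _random_rotation(rng)
    if translation is None:
        translation = rng.uniform(-10.0, 10.0, 3)
    half = edge_length_m / 2.0
    corners_m = np.array([
        [-half, -half, 0.0], [half, -half, 0.0],
        [half, half, 0.0], [-half, half, 0.0]])
    corners = (corners_m * scale) @ np.asarray(rotation).T + np.asarray(translation)
    if corner_noise_sigma > 0:
        corners = corners + rng.normal(0.0, corner_noise_sigma, corners.shape)
    return MarkerObservation(corners, physical_edge_length=edge_length_m)


def one_sided_cut(fixture: PlantFixture, view_direction, min_dot: float = 0.0) -> PlantFixture:
    """Remove points whose surface normal faces away from the camera.

    Emulates the failure mode of curled organs under one-sided capture:
    the far side is never imaged, so its points are absent."""
    if fixture.normals is None:
        raise ValueError("fixture carries no normals; cannot apply capture cut")
    view = np.asarray(view_direction, dtype=float)
    view = view / np.linalg.norm(view)
    keep = fixture.normals @ view >= min_dot
    capture = dict(fixture.capture)
    capture.update({"view_direction": tuple(view), "coverage": float(keep.mean())})
    return PlantFixture(
        fixture.cloud.select(keep), dict(fixture.truth), fixture.seed,
        capture, fixture.normals[keep])
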