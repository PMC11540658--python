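"""Core geometric containers: point clouds and triangle meshes.

Coordinates are dimensionless reconstruction units until a metric
calibration marks the cloud metric (``is_metric=True``), after which they
are meters.  Trait operations that report physical units refuse
non-metric input so unit errors fail loudly instead of silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud", "TriangleMesh", "NotMetricError"]


class NotMetricError(ValueError):
    """Raised when a physical-unit trait is requested on an uncalibrated cloud."""


def _as_points(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if out.size == 0:
        return out.reshape(0, 3)
    if out.ndim != 2 or out.shape[1] != 3:
        raise ValueError(f"{name} must have shape (N, 3), got {out.shape}")
    if not np.all(np.isfinite(out)):
        bad = int(np.flatnonzero(~np.isfinite(out).all(axis=1))[0])
        raise ValueError(f"{name} contains a non-finite coordinate at row {bad}")
    return out


@dataclass
class PointCloud:
    """N unorganized 3D points with optional per-point RGB colors.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates, meters when ``is_metric`` is true, reconstruction
        units otherwise.
    colors : (N, 3) float array in [0, 1], optional
    is_metric : bool
        Whether coordinates are in meters.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    is_metric: bool = False

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, "points")
        if self.colors is not None:
            colors = np.asarray(self.colors, dtype=np.float64)
            if colors.size == 0:
                colors = colors.reshape(0, 3)
            if colors.shape != self.points.shape:
                raise ValueError(
                    f"colors shape {colors.shape} does not match "
                    f"points shape {self.points.shape}"
                )
            if colors.size and (colors.min() < 0.0 or colors.max() > 1.0):
                raise ValueError("colors must lie in [0, 1]")
            self.colors = colors

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, mask_or_index) -> "PointCloud":
        """Subset by boolean mask or integer index, preserving order."""
        pts = self.points[mask_or_index]
        cols = None if self.colors is None else self.colors[mask_or_index]
        return PointCloud(pts, cols, self.is_metric)

    def with_points(self, points: np.ndarray, *, is_metric: bool | None = None) -> "PointCloud":
        """Same colors/flags with replaced coordinates (count must match)."""
        pts = _as_points(points, "points")
        if pts.shape[0] != len(self):
            raise ValueError("replacement point count differs")
        return PointCloud(
            pts, None if self.colors is None else self.colors.copy(),
            self.is_metric if is_metric is None else is_metric,
        )

    def require_metric(self, op: str) -> None:
        if not self.is_metric:
            raise NotMetricError(
                f"{op} reports physical units and requires a metric cloud; "
                "apply a scale calibration first (metric_calibration.apply_scale)"
            )

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.colors is None else self.colors.copy(),
            self.is_metric,
        )


@dataclass
class TriangleMesh:
    """Triangle soup: vertices plus integer face triples.

    Open, non-manifold surfaces are permitted — leaves are bordered open
    surfaces, so watertightness is never required.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.intp))

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        faces = np.asarray(self.faces, dtype=np.intp)
        if faces.size == 0:
            faces = faces.reshape(0, 3)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError(f"faces must have shape (M, 3), got {faces.shape}")
        n = self.vertices.shape[0]
        if faces.size:
            if faces.min() < 0 or faces.max() >= n:
                raise ValueError("face index out of range")
            a, b, c = faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("a face references the same vertex twice")
        self.faces = faces

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def triangle_areas(self) -> np.ndarray:
        """Per-face area: half the cross-product magnitude of two edges."""
        if self.n_faces == 0:
            return np.empty(0)
        v = self.vertices
        p0, p1, p2 = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())
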