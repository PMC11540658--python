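"""Programmatic organ segmentation of plant point clouds.

Replaces interactive clipping with two reproducible region primitives:
an axis-aligned box (inclusive bounds, like a cuboid clip) and a polygon
projected orthographically along a stored view direction (the scripted
analogue of drawing a lasso on screen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .cloud import PointCloud

__all__ = ["BoxRegion", "PolygonRegion", "crop"]


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box; both bounds inclusive."""

    minimum: tuple[float, float, float]
    maximum: tuple[float, float, float]

    def __post_init__(self):
        lo = np.asarray(self.minimum, dtype=float)
        hi = np.asarray(self.maximum, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("box bounds must be length-3")
        if np.any(lo > hi):
            raise ValueError("box minimum exceeds maximum on some axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.minimum)
        hi = np.asarray(self.maximum)
        return np.all((points >= lo) & (points <= hi), axis=1)


@dataclass(frozen=True)
class PolygonRegion:
    """Planar polygon swept along ``view_direction``.

    A point is kept when its orthographic projection along the view
    direction lands strictly inside the polygon.  ``vertices`` are 2D
    coordinates in the projection plane's basis.
    """

    vertices: tuple  # sequence of (u, v) pairs
    view_direction: tuple[float, float, float]

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs >= 3 two-dimensional vertices")
        # collinearity check via the shoelace area
        x, y = verts[:, 0], verts[:, 1]
        area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area2 <= 1e-300:
            raise ValueError("polygon vertices are collinear")
        d = np.asarray(self.view_direction, dtype=float)
        if d.shape != (3,) or not np.linalg.norm(d) > 0:
            raise ValueError("view_direction must be a nonzero 3-vector")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Right-handed orthonormal (u, v) spanning the projection plane."""
        w = np.asarray(self.view_direction, dtype=float)
        w = w / np.linalg.norm(w)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(w[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(helper, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return u, v

    def contains(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        poly = shapely.Polygon(np.asarray(self.vertices, dtype=float))
        return shapely.contains_xy(poly, points @ u, points @ v)


def crop(cloud: PointCloud, region) -> PointCloud:
    """Return exactly the points inside ``region``, order and colors kept.

    An empty result is valid (no error)."""
    if len(cloud) == 0:
        return cloud.copy()
    return cloud.select(region.contains(cloud.points))
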