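"""Metric scale calibration from a marker of known physical size.

Structure-from-motion reconstructions are defined only up to a global
similarity, so coordinates come out in arbitrary "reconstruction units".
Placing a printed square marker of known edge length (0.30 m in the
greenhouse protocol) in one captured scene and locating its corners in
the reconstruction fixes the scale: each marker edge yields a ratio
physical / reconstructed length, and their mean is the meters-per-unit
scale factor.  Edge ratios need no registration to a canonical marker
frame, so the estimate is invariant to any rigid motion of the corners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import PointCloud

__all__ = [
    "MarkerObservation",
    "ScaleCalibration",
    "estimate_scale",
    "apply_scale",
    "DEFAULT_MARKER_EDGE_M",
]

#: Edge length of the printed square calibration marker, meters.
DEFAULT_MARKER_EDGE_M = 0.30


@dataclass
class MarkerObservation:
    """Reconstructed marker corners plus which pairs are physical edges.

    ``reconstructed_corners`` are >= 2 corner positions in reconstruction
    units; ``corner_adjacency`` lists index pairs joined by a marker edge
    of length ``physical_edge_length`` meters.
    """

    reconstructed_corners: np.ndarray
    physical_edge_length: float = DEFAULT_MARKER_EDGE_M
    corner_adjacency: tuple = ((0, 1), (1, 2), (2, 3), (3, 0))

    def __post_init__(self):
        corners = np.asarray(self.reconstructed_corners, dtype=np.float64)
        if corners.ndim != 2 or corners.shape[1] != 3 or corners.shape[0] < 2:
            raise ValueError("need >= 2 reconstructed 3D corners")
        self.reconstructed_corners = corners
        if self.physical_edge_length <= 0:
            raise ValueError("physical_edge_length must be positive")
        adjacency = tuple((int(i), int(j)) for i, j in self.corner_adjacency)
        n = corners.shape[0]
        for i, j in adjacency:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid corner pair ({i}, {j})")
        if not adjacency:
            raise ValueError("at least one adjacent corner pair is required")
        self.corner_adjacency = adjacency

    def edge_lengths(self) -> np.ndarray:
        c = self.reconstructed_corners
        return np.array([
            np.linalg.norm(c[j] - c[i]) for i, j in self.corner_adjacency
        ])


@dataclass
class ScaleCalibration:
    """Meters per reconstruction unit, with the per-edge residual spread."""

    scale_factor: float
    residual_rms: float = 0.0
    marker_edge_m: float = DEFAULT_MARKER_EDGE_M

    def __post_init__(self):
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "scale_factor": self.scale_factor,
            "residual_rms": self.residual_rms,
            "marker_edge_m": self.marker_edge_m,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "ScaleCalibration":
        d = json.loads(Path(path).read_text())
        return cls(d["scale_factor"], d.get("residual_rms", 0.0),
                   d.get("marker_edge_m", DEFAULT_MARKER_EDGE_M))


def estimate_scale(obs: MarkerObservation) -> ScaleCalibration:
    """Mean per-edge ratio of physical to reconstructed edge length.

    ``residual_rms`` is the RMS mismatch, in meters, between the physical
    edge length and each reconstructed edge after scaling.
    """
    lengths = obs.edge_lengths()
    if np.any(lengths <= 0):
        raise ValueError("degenerate marker: zero-length reconstructed edge")
    scale = float(np.mean(obs.physical_edge_length / lengths))
    residual = float(np.sqrt(np.mean(
        (obs.physical_edge_length - scale * lengths) ** 2)))
    return ScaleCalibration(scale, residual, obs.physical_edge_length)


def apply_scale(cloud: PointCloud, cal: ScaleCalibration) -> PointCloud:
    """Multiply every coordinate by the scale factor and mark the cloud metric.

    Refuses already-metric clouds — a second application would silently
    double-scale."""
    if cloud.is_metric:
        raise ValueError("cloud is already metric; refusing to re-scale")
    return cloud.with_points(cloud.points * cal.scale_factor, is_metric=True)
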