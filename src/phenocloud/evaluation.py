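"""Ground-truth helpers and the predicted-vs-truth evaluation harness.

Ground truth in a greenhouse survey comes from destructive or manual
measurements: leaf silhouettes photographed against a ruler (pixel area
times a cm-per-pixel scale) and fruit volumes from the buoyancy method
(the scale reading in grams of a fully submerged fruit equals its volume
in cm^3 for unit-density water).  Agreement between pipeline predictions
and such truth is summarized by the coefficient of determination
r^2 = 1 - SS_res / SS_tot (about the truth mean) and the mean absolute
percentage error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EvalSummary", "evaluate", "silhouette_leaf_area", "buoyancy_volume"]


@dataclass(frozen=True)
class EvalSummary:
    """Agreement between predicted and ground-truth trait values."""

    r_squared: float
    mape: float        # mean absolute percentage error, as a fraction
    n: int

    def __post_init__(self):
        if self.mape < 0:
            raise ValueError("mape must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 pairs")


def evaluate(predicted, truth) -> EvalSummary:
    """r^2 and MAPE of predictions against ground truth.

    r^2 is 1 - SS_res/SS_tot about the truth mean (the
    regression-through-data convention for predicted-vs-truth scatter),
    not squared Pearson correlation.  Pairs with zero truth are excluded
    from the MAPE with a warning."""
    pred = np.asarray(predicted, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if pred.shape != tru.shape or pred.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1D sequences")
    n = pred.size
    if n < 2:
        raise ValueError("need at least 2 pairs")

    ss_res = float(np.sum((tru - pred) ** 2))
    ss_tot = float(np.sum((tru - tru.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot

    nonzero = tru != 0
    if not np.all(nonzero):
        warnings.warn(
            f"{int((~nonzero).sum())} zero-truth pair(s) excluded from MAPE",
            stacklevel=2)
    if not np.any(nonzero):
        raise ValueError("no nonzero truth values; MAPE undefined")
    mape = float(np.mean(np.abs(pred[nonzero] - tru[nonzero]) / np.abs(tru[nonzero])))
    return EvalSummary(r_squared=r2, mape=mape, n=n)


def silhouette_leaf_area(image, pixels_per_cm: float) -> float:
    """Leaf area in cm^2 from a binary silhouette and a ruler-derived scale.

    ``image`` is a 2D binary array (or a path to one); foreground pixels
    are nonzero.  Area = foreground count / pixels_per_cm^2."""
    if pixels_per_cm <= 0:
        raise ValueError("pixels_per_cm must be positive")
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        import imageio.v3 as iio

        image = iio.imread(image)
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got shape {arr.shape}")
    values = np.unique(arr)
    if values.size > 2:
        raise ValueError(
            f"image is not binary: {values.size} distinct values")
    foreground = int(np.count_nonzero(arr))
    return foreground / pixels_per_cm**2


def buoyancy_volume(scale_reading_g: float, water_density: float = 1.0) -> float:
    """Fruit volume in cm^3 from the submersion scale reading in grams.

    Fully submerging a fruit adds a buoyant reaction equal to the weight
    of displaced water, so reading / water density [g/cm^3] is the
    displaced — hence fruit — volume."""
    if scale_reading_g < 0:
        raise ValueError("scale reading must be non-negative")
    if water_density <= 0:
        raise ValueError("water density must be positive")
    return scale_reading_g / water_density
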