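"""Agreement metrics between lesion probability maps.

Used to validate that lesion maps derived from two different scanners (or
segmentation pipelines) cover the same anatomy: the Dice coefficient of the
binarized maps and the mean square error of the probability values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridMismatchError
from .lpm import LesionProbabilityMap

__all__ = [
    "SimilarityReport",
    "dice_coefficient",
    "mean_square_error",
    "similarity_report",
]

DEFAULT_THRESHOLDS = (0.0, 0.01, 0.05, 0.1)


@dataclass(frozen=True)
class SimilarityReport:
    """Dice/MSE between two maps at one binarization threshold."""

    dice: float
    mse: float
    binarization_threshold: float
    n_a: int
    n_b: int
    n_intersection: int


def _check_grids(map_a: LesionProbabilityMap, map_b: LesionProbabilityMap) -> None:
    if map_a.grid is not None and map_b.grid is not None and not map_a.grid.matches(map_b.grid):
        raise GridMismatchError("maps are not on the same grid")
    if map_a.volume.shape != map_b.volume.shape:
        raise GridMismatchError("maps have different shapes")


def dice_coefficient(
    map_a: LesionProbabilityMap, map_b: LesionProbabilityMap, threshold: float = 0.0
) -> float:
    """Dice = 2|A∩B| / (|A|+|B|) after binarizing each map at value > threshold.

    Symmetric in its inputs.  Two empty binarized maps are defined as
    perfectly overlapping (Dice 1, with a warning).
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    _check_grids(map_a, map_b)
    a = map_a.volume > threshold
    b = map_b.volume > threshold
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both maps are empty after binarization; Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def mean_square_error(
    map_a: LesionProbabilityMap,
    map_b: LesionProbabilityMap,
    support_mask: np.ndarray | None = None,
) -> float:
    """Mean of (A - B)^2 over the analysis support.

    By default the support is the union of the two maps' nonzero voxels (so
    empty background does not dilute the metric); pass ``support_mask`` to
    evaluate over an explicit mask (e.g. whole brain or a WM mask) instead.
    """
    _check_grids(map_a, map_b)
    diff2 = (map_a.volume - map_b.volume) ** 2
    if support_mask is None:
        support_mask = (map_a.volume > 0) | (map_b.volume > 0)
    else:
        support_mask = np.asarray(support_mask, dtype=bool)
        if support_mask.shape != diff2.shape:
            raise GridMismatchError("support mask does not match the maps")
    if not support_mask.any():
        return 0.0
    return float(diff2[support_mask].mean())


def similarity_report(
    map_a: LesionProbabilityMap,
    map_b: LesionProbabilityMap,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    support_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Dice across binarization thresholds plus MSE, as a tidy table."""
    mse = mean_square_error(map_a, map_b, support_mask=support_mask)
    rows = []
    for thr in thresholds:
        a = map_a.volume > thr
        b = map_b.volume > thr
        rows.append({
            "threshold": thr,
            "dice": dice_coefficient(map_a, map_b, thr),
            "mse": mse,
            "n_a": int(a.sum()),
            "n_b": int(b.sum()),
            "n_intersection": int((a & b).sum()),
        })
    return pd.DataFrame(rows)
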