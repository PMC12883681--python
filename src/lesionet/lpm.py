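"""Lesion probability maps and nonparametric between-group lesion comparison.

A lesion probability map (LPM) is the voxel-wise fraction of subjects in a
group whose binary lesion mask covers that voxel.  Group comparisons run
the shared permutation GLM on the stacked binary masks, restricted to white
matter (probability > 0.25) and to voxels lesioned in at least a couple of
subjects overall (degenerate variance otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .inference import DesignMatrix, InferenceSettings, PermutationResult, permutation_inference

__all__ = [
    "BinaryLesionMask",
    "LesionProbabilityMap",
    "compute_lpm",
    "compare_lesion_probability",
    "WM_PROBABILITY_THRESHOLD",
]

#: white matter probability threshold for the lesion analysis mask
WM_PROBABILITY_THRESHOLD = 0.25
#: voxels lesioned in fewer subjects than this (pooled) are not tested
MIN_LESIONED_SUBJECTS = 2


@dataclass
class BinaryLesionMask:
    """Per-patient binary lesion mask on the shared grid."""

    subject_id: str
    volume: np.ndarray = field(repr=False)
    grid: VolumeGrid = None

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume)
        if not np.isin(vol, (0, 1)).all():
            bad = int(np.sum(~np.isin(vol, (0, 1))))
            raise ValueError(
                f"lesion mask {self.subject_id} is not binary ({bad} offending values)"
            )
        self.volume = vol.astype(np.uint8)
        if self.grid is not None and self.volume.shape != self.grid.shape:
            raise ValueError(f"mask {self.subject_id} does not match its grid")

    @property
    def is_empty(self) -> bool:
        return not self.volume.any()

    @property
    def n_lesioned(self) -> int:
        return int(self.volume.sum())

    def lesion_volume_ml(self) -> float:
        """Total lesion volume in millilitres (voxel volume from the affine)."""
        return self.n_lesioned * float(np.prod(self.grid.voxel_size)) / 1000.0


@dataclass
class LesionProbabilityMap:
    """Voxel-wise lesion frequency for one group of subjects."""

    group: str
    volume: np.ndarray = field(repr=False)
    n_subjects: int = 0
    grid: VolumeGrid = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("lesion probabilities must lie in [0, 1]")
        if self.n_subjects > 0:  # 0 = unknown provenance (e.g. map loaded from disk)
            counts = v * self.n_subjects
            if not np.allclose(counts, np.round(counts), atol=1e-9):
                raise ValueError("every LPM value times n_subjects must be an integer")
        self.volume = v


def _check_shared_grid(masks: list[BinaryLesionMask]) -> VolumeGrid:
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid is None or not grid.matches(m.grid):
            from .grid import GridMismatchError
            raise GridMismatchError(f"mask of subject {m.subject_id} is not on the shared grid")
    return grid


def compute_lpm(masks: list[BinaryLesionMask], group: str = "") -> LesionProbabilityMap:
    """Average binary masks into a lesion probability map.

    Raises on an empty list or a grid mismatch (naming the offending
    subject).  Empty individual masks are allowed.
    """
    if not masks:
        raise ValueError("need at least one mask")
    grid = _check_shared_grid(masks)
    stacked = np.stack([m.volume for m in masks]).astype(float)
    return LesionProbabilityMap(
        group=group, volume=stacked.mean(axis=0), n_subjects=len(masks), grid=grid
    )


def compare_lesion_probability(
    masks_a: list[BinaryLesionMask],
    masks_b: list[BinaryLesionMask],
    covariates: pd.DataFrame | None,
    wm_probability: np.ndarray,
    settings: InferenceSettings,
    atlas=None,
    min_lesioned_subjects: int = MIN_LESIONED_SUBJECTS,
) -> PermutationResult:
    """Covariate-adjusted nonparametric voxel-wise lesion-frequency comparison.

    The contrast direction ``pos`` is B > A (more frequent lesions in group
    B); ``neg`` is the opposite.  Analysis voxels must have white matter
    probability above 0.25 and lesions in at least ``min_lesioned_subjects``
    pooled subjects.

    Parameters
    ----------
    masks_a, masks_b : lists of BinaryLesionMask
        The two groups (each of size >= 2).
    covariates : DataFrame or None
        Nuisance columns (e.g. age, sex, EDSS, scanner), rows ordered as
        ``masks_a + masks_b``.
    wm_probability : ndarray
        White matter probability volume on the shared grid.
    settings : InferenceSettings
    """
    if len(masks_a) < 2 or len(masks_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    masks = list(masks_a) + list(masks_b)
    grid = _check_shared_grid(masks)
    wm_probability = np.asarray(wm_probability, dtype=float)
    if wm_probability.shape != grid.shape:
        raise ValueError("white matter probability volume does not match the grid")
    stacked = np.stack([m.volume for m in masks]).astype(float)
    pooled_count = stacked.sum(axis=0)
    mask = (wm_probability > WM_PROBABILITY_THRESHOLD) & (pooled_count >= min_lesioned_subjects)
    if not mask.any():
        raise ValueError("no analyzable voxels after white matter and lesion-count masking")
    group = np.concatenate([np.zeros(len(masks_a)), np.ones(len(masks_b))])
    design = DesignMatrix.two_group(group, covariates)
    return permutation_inference(stacked, design, settings, grid, mask, atlas=atlas)
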