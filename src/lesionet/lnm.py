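"""Lesion network mapping against a normative functional connectome.

Each patient's binary lesion mask seeds a resting-state functional
connectivity analysis in every normative subject: the mean time course over
lesioned voxels is correlated with every brain voxel's time course and the
correlations are Fisher r-to-z transformed.  The per-normative-subject z
maps are aggregated with a one-sample t-test; the resulting t volume is the
patient's lesion network map (LNM) — a map of regions functionally
connected to that patient's lesion locations.  Group comparisons of LNMs
run the shared permutation GLM inside a gray matter mask (probability >
0.25) with age, sex, EDSS, scanner and log lesion volume as nuisance
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .inference import DesignMatrix, InferenceSettings, PermutationResult, permutation_inference
from .lpm import BinaryLesionMask

__all__ = [
    "NormativeScan",
    "LesionNetworkMap",
    "extract_seed_timecourse",
    "lesion_fc_map",
    "fisher_z",
    "compute_lnm",
    "compare_lnm_groups",
    "GM_PROBABILITY_THRESHOLD",
]

#: gray matter probability threshold for the LNM analysis mask
GM_PROBABILITY_THRESHOLD = 0.25
#: correlations are clipped to +/- (1 - eps) before atanh
FISHER_CLIP_EPS = 1e-7


@dataclass
class NormativeScan:
    """One normative subject's resting-state series, time-major (T, x, y, z)."""

    subject_id: str
    series: np.ndarray = field(repr=False)
    grid: VolumeGrid = None

    def __post_init__(self) -> None:
        s = np.asarray(self.series)
        if s.ndim != 4:
            raise ValueError("series must be 4D (time, x, y, z)")
        if s.shape[0] < 3:
            raise ValueError("need at least 3 timepoints for a defined correlation")
        if not np.isfinite(s).all():
            raise ValueError(f"scan {self.subject_id} contains non-finite values")
        if self.grid is not None and s.shape[1:] != self.grid.shape:
            raise ValueError(f"scan {self.subject_id} does not match its grid")
        self.series = s

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]


@dataclass
class LesionNetworkMap:
    """Per-patient 3D t map over normative-subject Fisher-z connectivity maps.

    ``degenerate`` flags voxels whose z values had zero variance across
    normative subjects (their t is set to 0, not dropped silently).
    """

    subject_id: str
    volume: np.ndarray = field(repr=False)
    n_normative: int = 0
    grid: VolumeGrid = None
    degenerate: np.ndarray = None


def extract_seed_timecourse(scan: NormativeScan, mask: BinaryLesionMask) -> np.ndarray:
    """Mean time course over the lesioned (seed) voxels."""
    if mask.is_empty:
        raise ValueError("empty seed: lesion mask has no voxels")
    if scan.grid is not None and mask.grid is not None:
        scan.grid.check_same(mask.grid, what=f"seed of {mask.subject_id}")
    seed = mask.volume.astype(bool)
    return scan.series[:, seed].mean(axis=1)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z: atanh with clipping at +/- (1 - 1e-7) to stay finite."""
    return np.arctanh(np.clip(r, -1.0 + FISHER_CLIP_EPS, 1.0 - FISHER_CLIP_EPS))


def lesion_fc_map(scan: NormativeScan, seed_tc: np.ndarray) -> np.ndarray:
    """Voxel-wise Fisher-z correlation of the scan with a seed time course.

    Pearson r of every voxel's series with ``seed_tc``, then r-to-z.
    Voxels with a constant series get r = 0 (z = 0); a constant seed time
    course is an error.
    """
    seed_tc = np.asarray(seed_tc, dtype=float)
    if seed_tc.ndim != 1 or len(seed_tc) != scan.n_timepoints:
        raise ValueError("seed time course length must match the scan")
    sc = seed_tc - seed_tc.mean()
    seed_ss = float(sc @ sc)
    if seed_ss <= 0:
        raise ValueError("seed time course is constant")
    data = scan.series.reshape(scan.n_timepoints, -1).astype(float)
    data = data - data.mean(axis=0)
    cov = sc @ data
    voxel_ss = np.einsum("ij,ij->j", data, data)
    r = np.zeros(data.shape[1])
    ok = voxel_ss > 0
    r[ok] = cov[ok] / np.sqrt(voxel_ss[ok] * seed_ss)
    return fisher_z(r).reshape(scan.series.shape[1:])


def compute_lnms(
    masks: list[BinaryLesionMask], connectome: list[NormativeScan]
) -> list[LesionNetworkMap]:
    """Lesion network maps for a whole cohort against one connectome.

    Equivalent to calling :func:`compute_lnm` per mask, but demeans each
    normative scan once and correlates all seed time courses against it in
    a single matrix product, which is what makes cohort-scale runs cheap.
    """
    if len(connectome) < 2:
        raise ValueError("need at least 2 normative scans")
    if not masks:
        return []
    grid = connectome[0].grid
    shape = connectome[0].series.shape[1:]
    seeds = []
    for m in masks:
        if m.is_empty:
            raise ValueError(f"empty seed: lesion mask {m.subject_id} has no voxels")
        seeds.append(m.volume.astype(bool).reshape(-1))
    n_masks = len(masks)
    n_vox = int(np.prod(shape))
    zsum = np.zeros((n_masks, n_vox))
    zsq = np.zeros((n_masks, n_vox))
    for scan in connectome:
        if grid is not None and scan.grid is not None:
            grid.check_same(scan.grid, what=f"scan {scan.subject_id}")
        data = scan.series.reshape(scan.n_timepoints, -1).astype(float)
        data = data - data.mean(axis=0)
        voxel_ss = np.einsum("ij,ij->j", data, data)
        ok = voxel_ss > 0
        seed_tcs = np.stack([data[:, s].mean(axis=1) for s in seeds])  # (n_masks, T)
        seed_ss = np.einsum("ij,ij->i", seed_tcs, seed_tcs)
        if np.any(seed_ss <= 0):
            bad = masks[int(np.argmin(seed_ss))].subject_id
            raise ValueError(f"seed time course of {bad} is constant in scan {scan.subject_id}")
        cov = seed_tcs @ data  # (n_masks, n_vox)
        r = np.zeros_like(cov)
        denom = np.sqrt(seed_ss[:, None] * voxel_ss[None, ok])
        r[:, ok] = cov[:, ok] / denom
        z = fisher_z(r)
        zsum += z
        zsq += z * z
    n = len(connectome)
    mean = zsum / n
    # n-1 variance; guard tiny negatives from the sum-of-squares form
    var = np.maximum(zsq - n * mean * mean, 0.0) / (n - 1)
    sd = np.sqrt(var)
    degenerate = sd <= 1e-12
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~degenerate)
    return [
        LesionNetworkMap(
            subject_id=m.subject_id,
            volume=t[i].reshape(shape),
            n_normative=n,
            grid=grid,
            degenerate=degenerate[i].reshape(shape),
        )
        for i, m in enumerate(masks)
    ]


def compute_lnm(mask: BinaryLesionMask, connectome: list[NormativeScan]) -> LesionNetworkMap:
    """One patient's lesion network map from a normative connectome.

    Per voxel, a one-sample t over the normative subjects' Fisher-z values:
    ``t = mean(z) / (sd(z) / sqrt(n))`` with the n-1 SD denominator.
    Deterministic: permuting the order of the normative scans leaves the
    output unchanged.
    """
    return compute_lnms([mask], connectome)[0]


def compare_lnm_groups(
    lnms_a: list[LesionNetworkMap],
    lnms_b: list[LesionNetworkMap],
    covariates: pd.DataFrame | None,
    gm_probability: np.ndarray,
    settings: InferenceSettings,
    atlas=None,
    log_transform_t2lv: bool = True,
) -> PermutationResult:
    """Covariate-adjusted permutation comparison of lesion network maps.

    ``pos`` is B > A (lesions of group B more connected to a voxel).
    Restricted to gray matter probability > 0.25.  A ``t2lv`` covariate
    column, if present, is entered log-transformed.
    """
    if len(lnms_a) < 2 or len(lnms_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    maps = list(lnms_a) + list(lnms_b)
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid is None or not grid.matches(m.grid):
            from .grid import GridMismatchError
            raise GridMismatchError(f"LNM of subject {m.subject_id} is not on the shared grid")
    gm_probability = np.asarray(gm_probability, dtype=float)
    if gm_probability.shape != grid.shape:
        raise ValueError("gray matter probability volume does not match the grid")
    mask = gm_probability > GM_PROBABILITY_THRESHOLD
    if not mask.any():
        raise ValueError("gray matter mask is empty at threshold 0.25")
    if covariates is not None and log_transform_t2lv and "t2lv" in covariates.columns:
        covariates = covariates.copy()
        # floor at 0.001 mL (a fraction of one voxel) so lesion-free subjects stay finite
        covariates["t2lv"] = np.log(np.maximum(np.asarray(covariates["t2lv"], dtype=float), 1e-3))
    stacked = np.stack([m.volume for m in maps]).astype(float)
    group = np.concatenate([np.zeros(len(lnms_a)), np.ones(len(lnms_b))])
    design = DesignMatrix.two_group(group, covariates)
    return permutation_inference(stacked, design, settings, grid, mask, atlas=atlas)
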