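"""Voxel-wise GLM with permutation-based familywise error control.

This is the statistical engine shared by the lesion-probability-map and
lesion-network-map group comparisons.  A per-voxel general linear model with
a single contrast of interest (typically a 0/1 group indicator) and nuisance
covariates (age, sex, disability, scanner, lesion volume) is combined with
Freedman–Lane permutation of nuisance-model residuals.  Two familywise error
corrections are computed from the same permutation stream:

* voxel-level FWE: the null distribution of the maximum t over the analysis
  mask;
* cluster-extent FWE: suprathreshold clusters are formed at an uncorrected
  per-voxel threshold (Student reference at the model's residual degrees of
  freedom) and the null distribution of the maximum cluster extent is used
  to correct each observed cluster.

Both one-sided directions of the contrast are evaluated in one pass.  All
permutation p-values use the add-one convention ``(1 + #{perm >= obs}) /
(1 + n_perm)`` with the observed labelling always included, so no p-value is
ever exactly zero; ties count against the observed statistic (conservative).
When fewer distinct relabellings exist than permutations requested, the
engine falls back to complete enumeration and the p-values are exact.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "InferenceSettings",
    "StatMap",
    "ClusterTable",
    "PermutationResult",
    "glm_tmap",
    "permutation_inference",
    "extract_clusters",
]


class RankDeficientDesignError(ValueError):
    """Design matrix does not have full column rank."""


def _find_collinear_column(X: np.ndarray, names: list[str]) -> str:
    """Name one column that is a linear combination of the others."""
    full_rank = np.linalg.matrix_rank(X)
    # scan from the end so a redundant covariate is named rather than the
    # intercept it happens to duplicate
    for j in reversed(range(X.shape[1])):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            return names[j]
    return names[-1]


@dataclass(frozen=True)
class DesignMatrix:
    """Subjects-by-regressors design with a single contrast of interest.

    Parameters
    ----------
    X : ndarray, shape (n_subjects, n_columns)
        Regressor matrix. Must have full column rank.
    names : list of str
        One name per column.
    contrast : ndarray, shape (n_columns,)
        Contrast vector c; the reported statistic is for c'beta > 0.
        Columns with a zero contrast weight are treated as nuisance for
        the Freedman–Lane permutation scheme.
    """

    X: np.ndarray = field(repr=False)
    names: tuple[str, ...]
    contrast: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        names = tuple(self.names)
        if X.ndim != 2:
            raise ValueError("design X must be 2D (subjects x columns)")
        if len(names) != X.shape[1]:
            raise ValueError("one name required per design column")
        if c.shape != (X.shape[1],):
            raise ValueError("contrast length must equal the number of design columns")
        if not np.any(c):
            raise ValueError("contrast is all zero")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficientDesignError(
                f"design is rank deficient; column '{_find_collinear_column(X, list(names))}' "
                "is collinear with the others"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "contrast", c)
        object.__setattr__(self, "names", names)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    @property
    def nuisance_columns(self) -> np.ndarray:
        """Indices of columns with zero contrast weight."""
        return np.flatnonzero(self.contrast == 0)

    @classmethod
    def two_group(
        cls,
        group: np.ndarray,
        covariates: pd.DataFrame | None = None,
        add_intercept: bool = True,
    ) -> "DesignMatrix":
        """Group indicator (coded 0/1) plus optional nuisance covariates.

        The contrast is +1 on the group column: positive t means group 1 >
        group 0.
        """
        group = np.asarray(group, dtype=float)
        if group.ndim != 1 or not np.isin(group, (0.0, 1.0)).all():
            raise ValueError("group must be a 1D 0/1 indicator")
        cols = [group]
        names = ["group"]
        if covariates is not None:
            for name in covariates.columns:
                cols.append(np.asarray(covariates[name], dtype=float))
                names.append(str(name))
        if add_intercept:
            cols.append(np.ones_like(group))
            names.append("intercept")
        X = np.column_stack(cols)
        contrast = np.zeros(X.shape[1])
        contrast[0] = 1.0
        return cls(X, tuple(names), contrast)

    def flipped(self) -> "DesignMatrix":
        """Same design, negated contrast (the opposite one-sided comparison)."""
        return replace(self, contrast=-self.contrast)


@dataclass(frozen=True)
class InferenceSettings:
    """Knobs of the permutation engine.

    Defaults mirror common practice for this analysis family: 5000
    permutations, cluster-forming p < 0.001, minimum cluster extent
    k_E = 50 voxels, familywise alpha 0.05, 18-connectivity (faces +
    edges) for cluster formation.  ``k_e_min`` is configurable because
    desk-scale grids are far smaller than a 2 mm MNI grid.
    """

    n_permutations: int = 5000
    cluster_forming_p: float = 0.001
    k_e_min: int = 50
    alpha: float = 0.05
    connectivity: int = 18
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_forming_p < self.alpha < 1.0):
            raise ValueError("need 0 < cluster_forming_p < alpha < 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")

    def cluster_structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class StatMap:
    """Voxel statistic map with permutation-corrected p-values.

    ``t`` is signed in the direction of the contrast this map reports;
    ``p_unc`` and ``p_fwe_voxel`` are one-sided permutation p-values for
    that direction.  Values outside ``mask`` are NaN (t) / 1 (p).
    Degenerate voxels (zero residual variance) carry t = 0 and are flagged
    in ``degenerate`` rather than silently dropped.
    """

    grid: VolumeGrid
    mask: np.ndarray
    t: np.ndarray
    p_unc: np.ndarray
    p_fwe_voxel: np.ndarray
    degenerate: np.ndarray
    df: int

    def __post_init__(self) -> None:
        inside = self.p_unc[self.mask]
        if inside.size and (np.any(inside <= 0) or np.any(inside > 1)):
            raise ValueError("uncorrected p-values must lie in (0, 1]")


CLUSTER_COLUMNS = [
    "cluster_id",
    "extent",
    "peak_i",
    "peak_j",
    "peak_k",
    "peak_x",
    "peak_y",
    "peak_z",
    "peak_t",
    "p_fwe_cluster",
    "labels",
]


@dataclass
class ClusterTable:
    """Suprathreshold clusters with extent-based FWE p-values and atlas labels.

    ``table`` is a DataFrame with one row per cluster (columns in
    ``CLUSTER_COLUMNS``), sorted by extent descending.  ``cluster_map`` is an
    int volume assigning each in-cluster voxel its cluster_id (0 elsewhere).
    """

    table: pd.DataFrame
    cluster_map: np.ndarray
    t_threshold: float
    k_e_min: int
    connectivity: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_fwe_cluster"] <= alpha]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        ids = self.significant(alpha)["cluster_id"].to_numpy()
        return np.isin(self.cluster_map, ids) & (self.cluster_map > 0)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class PermutationResult:
    """Both one-sided results of one permutation run.

    ``pos`` reports the contrast as given (c'beta > 0), ``neg`` the
    reversed direction.  ``exhaustive`` records whether the permutation
    distribution was enumerated completely (exact p-values).
    """

    pos: tuple[StatMap, ClusterTable]
    neg: tuple[StatMap, ClusterTable]
    settings: InferenceSettings
    n_permutations_used: int
    exhaustive: bool

    @property
    def df(self) -> int:
        return self.pos[0].df


# ---------------------------------------------------------------------------
# GLM t-field
# ---------------------------------------------------------------------------

_DEGENERATE_TOL = 1e-12


def _tmap_from_parts(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray,
                     pinvX: np.ndarray, cvar: float, df: int):
    """t-field for data Y (n, V) under design X; returns (t, degenerate)."""
    beta = pinvX @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    effect = contrast @ beta
    denom2 = sigma2 * cvar
    degenerate = denom2 <= _DEGENERATE_TOL * max(1.0, float(np.max(np.abs(Y), initial=1.0)) ** 2)
    t = np.zeros(Y.shape[1])
    ok = ~degenerate
    t[ok] = effect[ok] / np.sqrt(denom2[ok])
    return t, degenerate


def glm_tmap(data: np.ndarray, design: DesignMatrix):
    """Per-voxel least-squares contrast t statistic.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_voxels)
        One row per subject.
    design : DesignMatrix

    Returns
    -------
    t : ndarray, shape (n_voxels,)
        ``t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c)`` with residual
        df = n - n_columns. Degenerate voxels (zero residual variance)
        get t = 0.
    degenerate : ndarray of bool, shape (n_voxels,)
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("data must be 2D (subjects x voxels)")
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("data rows must match design rows")
    if design.df_resid < 2:
        raise ValueError("need n_subjects > n_columns + 1 for a stable variance estimate")
    pinvX = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    cvar = float(design.contrast @ xtx_inv @ design.contrast)
    return _tmap_from_parts(Y, X, design.contrast, pinvX, cvar, design.df_resid)


# ---------------------------------------------------------------------------
# Permutation schemes
# ---------------------------------------------------------------------------


def _intercept_only_nuisance(design: DesignMatrix) -> bool:
    """True when every nuisance column is constant (an intercept).

    In that case the permutation distribution of the t statistic depends on
    a relabelling only through which subjects carry which interest-column
    rows, so the distinct relabellings can be enumerated directly.
    """
    nz = design.nuisance_columns
    if nz.size == 0:
        return True
    return all(np.ptp(design.X[:, j]) == 0 for j in nz)


def _distinct_relabellings(design: DesignMatrix) -> int | None:
    """Number of distinct permutation statistics, when countable cheaply."""
    interest = np.flatnonzero(design.contrast != 0)
    if _intercept_only_nuisance(design) and interest.size == 1:
        col = design.X[:, interest[0]]
        values, counts = np.unique(col, return_counts=True)
        if len(values) == 2:
            return math.comb(len(col), int(counts[0]))
    n = design.n_subjects
    return math.factorial(n) if n <= 10 else None


def _iter_exhaustive_designs(design: DesignMatrix):
    """Yield permuted-interest design matrices covering every distinct split.

    Only valid when the nuisance is at most an intercept (see
    :func:`_intercept_only_nuisance`): then permuting the data rows is
    equivalent to permuting the interest column of the design.
    The identity labelling is yielded first.
    """
    interest = int(np.flatnonzero(design.contrast != 0)[0])
    col = design.X[:, interest]
    values = np.unique(col)
    hi = values[1]
    n_hi = int(np.sum(col == hi))
    n = len(col)
    observed = tuple(np.flatnonzero(col == hi))
    orderings = [observed] + [s for s in itertools.combinations(range(n), n_hi) if s != observed]
    for subset in orderings:
        newcol = np.full(n, values[0])
        newcol[list(subset)] = hi
        Xp = design.X.copy()
        Xp[:, interest] = newcol
        yield Xp


def _freedman_lane_parts(design: DesignMatrix):
    """Hat matrix of the nuisance-only model (for residual permutation)."""
    nz = design.nuisance_columns
    if nz.size == 0:
        n = design.n_subjects
        return np.zeros((n, n))
    Z = design.X[:, nz]
    return Z @ np.linalg.pinv(Z)


def _max_cluster_extent(binary_flat: np.ndarray, mask: np.ndarray,
                        structure: np.ndarray, scratch: np.ndarray) -> int:
    """Largest connected component of in-mask suprathreshold voxels."""
    scratch.fill(False)
    scratch[mask] = binary_flat
    if not scratch.any():
        return 0
    labels, n = ndimage.label(scratch, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------


def permutation_inference(
    data: np.ndarray,
    design: DesignMatrix,
    settings: InferenceSettings,
    grid: VolumeGrid,
    mask: np.ndarray,
    atlas=None,
) -> PermutationResult:
    """Permutation GLM with voxel-level and cluster-extent FWE correction.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, *grid.shape) or (n_subjects, n_mask_voxels)
        Per-subject volumes (or already-masked rows).
    design : DesignMatrix
    settings : InferenceSettings
    grid : VolumeGrid
    mask : ndarray of bool, shape grid.shape
        Analysis mask; statistics are computed only inside it.
    atlas : AtlasVolume, optional
        Used to label clusters (regions covering >= 5% of a cluster).

    Returns
    -------
    PermutationResult
        Stat maps and cluster tables for both one-sided directions.

    Notes
    -----
    The Freedman–Lane scheme is used: the nuisance-only model is fitted,
    its residuals are permuted, and the full model is refitted per
    permutation.  With at most an intercept as nuisance and a binary
    interest column, the engine instead enumerates the distinct group
    splits exactly when there are no more of them than permutations
    requested.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape must match the grid")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("analysis mask is empty")

    Y = np.asarray(data, dtype=float)
    if Y.ndim == 4:
        if Y.shape[1:] != grid.shape:
            raise ValueError("data volumes do not match the grid")
        Y = Y[:, mask]
    elif Y.ndim != 2 or Y.shape[1] != n_mask:
        raise ValueError("data must be (n, *grid.shape) or (n, n_mask_voxels)")

    X = design.X
    c = design.contrast
    df = design.df_resid
    pinvX = np.linalg.pinv(X)
    cvar = float(c @ np.linalg.inv(X.T @ X) @ c)
    t_obs, degenerate = _tmap_from_parts(Y, X, c, pinvX, cvar, df)
    t_thr = float(stats.t.isf(settings.cluster_forming_p, df))

    structure = settings.cluster_structure()
    scratch = np.zeros(grid.shape, dtype=bool)

    n_distinct = _distinct_relabellings(design)
    exhaustive = n_distinct is not None and n_distinct <= settings.n_permutations

    # streaming permutation bookkeeping
    ge_pos = np.zeros(n_mask, dtype=np.int64)   # {t* >= t_obs} per voxel
    ge_neg = np.zeros(n_mask, dtype=np.int64)
    max_t_pos: list[float] = []
    max_t_neg: list[float] = []
    max_ext_pos: list[int] = []
    max_ext_neg: list[int] = []

    def _record(t_perm: np.ndarray) -> None:
        ge_pos[:] += t_perm >= t_obs
        ge_neg[:] += -t_perm >= -t_obs
        max_t_pos.append(float(t_perm.max()))
        max_t_neg.append(float(-t_perm.min()))
        max_ext_pos.append(_max_cluster_extent(t_perm > t_thr, mask, structure, scratch))
        max_ext_neg.append(_max_cluster_extent(-t_perm > t_thr, mask, structure, scratch))

    if exhaustive and _intercept_only_nuisance(design):
        logger.info(
            "complete enumeration: %d distinct relabellings <= %d permutations requested",
            n_distinct, settings.n_permutations,
        )
        for Xp in _iter_exhaustive_designs(design):
            pinvXp = np.linalg.pinv(Xp)
            cvarp = float(c @ np.linalg.inv(Xp.T @ Xp) @ c)
            t_perm, _ = _tmap_from_parts(Y, Xp, c, pinvXp, cvarp, df)
            _record(t_perm)
        n_used = n_distinct
        denom = float(n_distinct)
    else:
        exhaustive = False
        rng = np.random.default_rng(settings.rng_seed)
        Hz = _freedman_lane_parts(design)
        fitted_z = Hz @ Y
        resid_z = Y - fitted_z
        _record(t_obs)  # the observed labelling is always included
        for _ in range(settings.n_permutations):
            perm = rng.permutation(design.n_subjects)
            Yp = fitted_z + resid_z[perm]
            t_perm, _ = _tmap_from_parts(Yp, X, c, pinvX, cvar, df)
            _record(t_perm)
        n_used = settings.n_permutations
        denom = float(settings.n_permutations + 1)

    # per-voxel p-values; with the observed labelling in the stream the
    # counts already include it, so p = count / denom is the add-one form
    p_unc_pos = ge_pos / denom
    p_unc_neg = ge_neg / denom
    sorted_max_pos = np.sort(max_t_pos)
    sorted_max_neg = np.sort(max_t_neg)
    # #{max_t* >= t_v} via sorted search (ties count against the observed value)
    p_fwe_pos = (len(sorted_max_pos) - np.searchsorted(sorted_max_pos, t_obs, side="left")) / denom
    p_fwe_neg = (len(sorted_max_neg) - np.searchsorted(sorted_max_neg, -t_obs, side="left")) / denom

    def _make_statmap(tvec, p_unc, p_fwe):
        t3 = np.full(grid.shape, np.nan)
        pu3 = np.ones(grid.shape)
        pf3 = np.ones(grid.shape)
        dg3 = np.zeros(grid.shape, dtype=bool)
        t3[mask] = tvec
        pu3[mask] = p_unc
        pf3[mask] = p_fwe
        dg3[mask] = degenerate
        return StatMap(grid=grid, mask=mask, t=t3, p_unc=pu3, p_fwe_voxel=pf3,
                       degenerate=dg3, df=df)

    sm_pos = _make_statmap(t_obs, p_unc_pos, p_fwe_pos)
    sm_neg = _make_statmap(-t_obs, p_unc_neg, p_fwe_neg)

    ct_pos = extract_clusters(sm_pos.t, mask, t_thr, settings, grid,
                              null_max_extents=np.asarray(max_ext_pos), denom=denom,
                              atlas=atlas)
    ct_neg = extract_clusters(sm_neg.t, mask, t_thr, settings, grid,
                              null_max_extents=np.asarray(max_ext_neg), denom=denom,
                              atlas=atlas)

    return PermutationResult(pos=(sm_pos, ct_pos), neg=(sm_neg, ct_neg),
                             settings=settings, n_permutations_used=n_used,
                             exhaustive=exhaustive)


def extract_clusters(
    t_field: np.ndarray,
    mask: np.ndarray,
    t_threshold: float,
    settings: InferenceSettings,
    grid: VolumeGrid,
    null_max_extents: np.ndarray | None = None,
    denom: float | None = None,
    atlas=None,
) -> ClusterTable:
    """Connected suprathreshold components with extent-FWE p and atlas labels.

    Components smaller than ``settings.k_e_min`` voxels are dropped.  When a
    permutation null of maximum extents is supplied, each surviving cluster
    gets ``p = #{max_extent* >= extent} / denom``; otherwise p is NaN.
    Clusters are labelled by every atlas region covering at least 5% of
    their voxels, sorted by overlap.
    """
    supra = np.zeros(grid.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        supra[mask] = t_field[mask] > t_threshold
    labels, n_comp = ndimage.label(supra, structure=settings.cluster_structure())
    rows = []
    cluster_map = np.zeros(grid.shape, dtype=np.int32)
    next_id = 0
    if n_comp:
        extents = np.bincount(labels.ravel())[1:]
        order = np.argsort(extents)[::-1]
        for comp in order:
            extent = int(extents[comp])
            if extent < settings.k_e_min:
                continue
            next_id += 1
            comp_mask = labels == comp + 1
            cluster_map[comp_mask] = next_id
            idx = np.argwhere(comp_mask)
            tvals = t_field[comp_mask]
            peak_local = int(np.argmax(tvals))
            peak_ijk = idx[peak_local]
            peak_xyz = grid.voxel_to_world(peak_ijk)
            if null_max_extents is not None:
                p_fwe = float((null_max_extents >= extent).sum() / denom)
            else:
                p_fwe = float("nan")
            if atlas is not None:
                from .io_atlas import lookup_labels
                label_str = "; ".join(
                    f"{name} ({frac * 100:.0f}%)"
                    for name, frac in lookup_labels(comp_mask, atlas)
                )
            else:
                label_str = ""
            rows.append({
                "cluster_id": next_id,
                "extent": extent,
                "peak_i": int(peak_ijk[0]),
                "peak_j": int(peak_ijk[1]),
                "peak_k": int(peak_ijk[2]),
                "peak_x": float(peak_xyz[0]),
                "peak_y": float(peak_xyz[1]),
                "peak_z": float(peak_xyz[2]),
                "peak_t": float(tvals[peak_local]),
                "p_fwe_cluster": p_fwe,
                "labels": label_str,
            })
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return ClusterTable(table=table, cluster_map=cluster_map,
                        t_threshold=t_threshold, k_e_min=settings.k_e_min,
                        connectivity=settings.connectivity)
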