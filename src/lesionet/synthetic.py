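"""Synthetic lesion cohorts, normative connectome and clinical scores.

Generates every input the pipeline needs, with planted ground truth, so the
whole analysis chain is testable end-to-end without any imaging download:

* binary lesion masks whose per-voxel lesion probability is exactly the
  configured field, raised by ``effect_delta`` inside the planted effect
  region for group B.  Lesions are contiguous blobs: a white-noise field is
  Gaussian-smoothed (FWHM 3 voxels), standardised by the exact per-voxel
  kernel norm, and thresholded at the Gaussian quantile matching the target
  probability — so the marginal law at each voxel is exact while spatial
  correlation makes lesions blob-like;
* 4D resting-state series in which the voxels of a seed region and of
  remote target regions share one latent standard-normal time course:
  ``x = coupling * latent + sqrt(1 - coupling^2) * noise`` (unit marginal
  variance, pairwise network correlation exactly coupling^2);
* clinical records whose raw test scores follow the normative regression
  plus a deficit proportional to the lesion load inside the effect region.

Determinism: every generator is a pure function of its config; per-subject
random streams are derived from the root seed by counter offset, so output
does not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .cohort import DOMAINS, TESTS, NormativeModel, SubjectRecord
from .grid import VolumeGrid
from .lnm import NormativeScan
from .lpm import BinaryLesionMask

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_grid",
    "default_phantom",
    "default_config",
    "simulate_lesion_cohort",
    "simulate_normative_connectome",
    "simulate_clinical_scores",
    "expected_pairwise_network_r",
    "expected_seed_mean_target_r",
    "count_matched_cohort",
    "IDENTITY_NORMS",
    "DEFAULT_TRUE_NORMS",
]

#: smoothing kernel for lesion blob generation, voxels
LESION_SMOOTHING_FWHM = 3.0

# stream identifiers for per-subject counter-offset seeding
_STREAM_LESION, _STREAM_CONNECTOME, _STREAM_CLINICAL = 0, 1, 2


def _subject_rng(root_seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(stream, index)))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generators need, with planted ground truth regions.

    ``base_lesion_field`` holds per-voxel lesion probabilities for group A;
    group B gets ``+ effect_delta`` inside ``effect_region``.  The network
    regions drive the synthetic connectome; ``network_coupling`` is the
    latent-signal weight (pairwise network-voxel correlation is its
    square).  ``score_effect`` is the z-shift per unit (fractional) lesion
    load in the effect region.
    """

    grid: VolumeGrid
    n_per_group: tuple[int, int]
    base_lesion_field: np.ndarray = field(repr=False)
    effect_region: np.ndarray = field(repr=False)
    effect_delta: float = 0.0
    network_seed_region: np.ndarray = field(repr=False, default=None)
    network_target_regions: np.ndarray = field(repr=False, default=None)
    network_coupling: float = 0.0
    n_normative: int = 20
    n_timepoints: int = 100
    score_effect: float = 0.0
    rng_seed: int = 0
    # clinical nuisance distributions (means/SDs chosen to emulate a large
    # adult MS cohort; exceedance of the fatigue/depression cut-offs lands
    # near the observed prevalence when left at defaults)
    mfis_mean: float = 32.5
    mfis_sd: float = 17.5
    madrs_mean: float = 7.5
    madrs_sd: float = 7.5
    missing_mfis_fraction: float = 0.17
    missing_madrs_fraction: float = 0.17

    def __post_init__(self) -> None:
        base = np.asarray(self.base_lesion_field, dtype=float)
        if base.shape != self.grid.shape:
            raise ValueError("base lesion field must live on the grid")
        if base.min() < 0 or base.max() > 1:
            raise ValueError("base lesion probabilities must lie in [0, 1]")
        effect = np.asarray(self.effect_region, dtype=bool)
        if effect.shape != self.grid.shape:
            raise ValueError("effect region must live on the grid")
        if not (0.0 <= self.effect_delta <= 1.0):
            raise ValueError("effect_delta must lie in [0, 1]")
        if np.any(base[effect] + self.effect_delta > 1.0 + 1e-12):
            raise ValueError("base + effect_delta exceeds 1 inside the effect region")
        if not (0.0 <= self.network_coupling < 1.0):
            raise ValueError("network_coupling must lie in [0, 1)")
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 timepoints (correlation degrees of freedom)")
        if self.n_normative < 2:
            raise ValueError("need at least 2 normative subjects")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        for name in ("network_seed_region", "network_target_regions"):
            region = getattr(self, name)
            if region is not None:
                region = np.asarray(region, dtype=bool)
                if region.shape != self.grid.shape:
                    raise ValueError(f"{name} must live on the grid")
                object.__setattr__(self, name, region)
        object.__setattr__(self, "base_lesion_field", base)
        object.__setattr__(self, "effect_region", effect)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    lesion_load: np.ndarray          # per subject: lesioned voxels in the effect region
    group_labels: np.ndarray         # 0 = group A, 1 = group B
    effect_region: np.ndarray
    target_mask: np.ndarray | None   # true network target voxels
    score_model: NormativeModel | None = None
    score_effect: float = 0.0

    def __post_init__(self) -> None:
        if len(self.lesion_load) != len(self.group_labels):
            raise ValueError("lesion_load and group_labels must have equal length")


# ---------------------------------------------------------------------------
# Default phantom geometry
# ---------------------------------------------------------------------------


def default_grid(n: int = 24, voxel_mm: float = 2.0) -> VolumeGrid:
    """Desk-scale cubic grid standing in for a 2 mm standard-space grid."""
    return VolumeGrid.isotropic((n, n, n), voxel_mm)


def _radius_field(grid: VolumeGrid) -> np.ndarray:
    center = (np.asarray(grid.shape) - 1) / 2.0
    idx = np.indices(grid.shape, dtype=float)
    return np.sqrt(sum((idx[a] - center[a]) ** 2 for a in range(3)))


def _sphere(grid: VolumeGrid, center_offset, radius: float) -> np.ndarray:
    center = (np.asarray(grid.shape) - 1) / 2.0 + np.asarray(center_offset, dtype=float)
    idx = np.indices(grid.shape, dtype=float)
    dist2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return dist2 <= radius**2


@dataclass(frozen=True)
class Phantom:
    """Geography of the synthetic head: tissue priors and planted regions.

    A central "white matter" ball (radius ~0.3 of the grid) carries the
    lesions; a surrounding "gray matter" shell carries the network target
    regions.  Tissue probabilities are 0.9 inside their compartment so the
    standard 0.25 analysis threshold reproduces the intended masks.
    """

    grid: VolumeGrid
    wm_probability: np.ndarray
    gm_probability: np.ndarray
    base_lesion_field: np.ndarray
    effect_region: np.ndarray
    network_seed_region: np.ndarray
    network_target_regions: np.ndarray


def default_phantom(grid: VolumeGrid | None = None, base_rate: float = 0.10) -> Phantom:
    grid = grid or default_grid()
    scale = min(grid.shape) / 24.0
    r = _radius_field(grid)
    wm_radius, brain_radius = 7.0 * scale, 11.0 * scale
    wm = np.where(r <= wm_radius, 0.9, 0.0)
    gm = np.where((r > wm_radius) & (r <= brain_radius), 0.9, 0.0)
    base = np.where(r <= wm_radius, base_rate, 0.0)
    effect = _sphere(grid, (3.0 * scale, 0.0, 0.0), 3.0 * scale) & (wm > 0)
    seed = _sphere(grid, (-3.5 * scale, 0.0, 0.0), 2.0 * scale) & (wm > 0)
    targets = (
        _sphere(grid, (0.0, 9.0 * scale, 0.0), 2.5 * scale)
        | _sphere(grid, (0.0, -9.0 * scale, 0.0), 2.5 * scale)
    ) & (gm > 0)
    return Phantom(grid, wm, gm, base, effect, seed, targets)


def default_config(
    n_per_group: tuple[int, int] = (40, 40),
    effect_delta: float = 0.0,
    network_coupling: float = 0.0,
    rng_seed: int = 0,
    grid: VolumeGrid | None = None,
    **kwargs,
) -> SimulationConfig:
    """Config on the default phantom; extra kwargs override any field."""
    phantom = default_phantom(grid)
    return SimulationConfig(
        grid=phantom.grid,
        n_per_group=tuple(n_per_group),
        base_lesion_field=phantom.base_lesion_field,
        effect_region=phantom.effect_region,
        effect_delta=effect_delta,
        network_seed_region=phantom.network_seed_region,
        network_target_regions=phantom.network_target_regions,
        network_coupling=network_coupling,
        rng_seed=rng_seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Lesion cohort
# ---------------------------------------------------------------------------


def _smoothing_sd_field(shape: tuple[int, ...], sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Exact per-voxel SD of zero-padded Gaussian-smoothed unit white noise.

    The kernel is separable, so the sum of squared weights inside the
    volume factorises into per-axis windowed sums of the squared 1D kernel.
    """
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    var = np.ones(shape)
    for axis, n in enumerate(shape):
        axis_var = ndimage.correlate1d(np.ones(n), k**2, mode="constant")
        shape_vec = [1, 1, 1]
        shape_vec[axis] = n
        var = var * axis_var.reshape(shape_vec)
    return np.sqrt(var)


def _one_lesion_mask(
    rng: np.random.Generator, prob_field: np.ndarray, sd_field: np.ndarray, sigma: float
) -> np.ndarray:
    noise = rng.standard_normal(prob_field.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="constant", truncate=4.0)
    z = smooth / sd_field  # exact N(0,1) marginal at every voxel
    with np.errstate(invalid="ignore"):
        threshold = stats.norm.isf(prob_field)  # +inf where p == 0
    return (z > threshold).astype(np.uint8)


def simulate_lesion_cohort(config: SimulationConfig):
    """Generate the two-group lesion cohort.

    Returns
    -------
    masks : list of BinaryLesionMask
        Group A subjects first, then group B.
    truth : GroundTruth
    """
    sigma = LESION_SMOOTHING_FWHM / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sd_field = _smoothing_sd_field(config.grid.shape, sigma)
    prob_a = config.base_lesion_field
    prob_b = prob_a + config.effect_delta * config.effect_region

    masks: list[BinaryLesionMask] = []
    n_a, n_b = config.n_per_group
    labels = np.concatenate([np.zeros(n_a, dtype=int), np.ones(n_b, dtype=int)])
    loads = np.zeros(config.n_subjects, dtype=int)
    for i in range(config.n_subjects):
        rng = _subject_rng(config.rng_seed, _STREAM_LESION, i)
        prob = prob_b if labels[i] else prob_a
        vol = _one_lesion_mask(rng, prob, sd_field, sigma)
        loads[i] = int(vol[config.effect_region].sum())
        masks.append(BinaryLesionMask(subject_id=f"sub-{i:04d}", volume=vol, grid=config.grid))
    truth = GroundTruth(
        lesion_load=loads,
        group_labels=labels,
        effect_region=config.effect_region.copy(),
        target_mask=None if config.network_target_regions is None
        else config.network_target_regions.copy(),
        score_effect=config.score_effect,
    )
    return masks, truth


# ---------------------------------------------------------------------------
# Normative connectome
# ---------------------------------------------------------------------------


def expected_pairwise_network_r(coupling: float) -> float:
    """Population correlation between two distinct network voxels.

    Both voxels are ``coupling * L + sqrt(1 - coupling^2) * noise`` with a
    shared latent L, so cov = coupling^2 and each variance is 1.
    """
    return coupling**2


def expected_seed_mean_target_r(coupling: float, n_seed_voxels: int) -> float:
    """Population correlation between a seed-region mean and a target voxel.

    Averaging m seed voxels keeps the latent part and shrinks the noise:
    var(mean) = coupling^2 + (1 - coupling^2)/m, cov with the target stays
    coupling^2.
    """
    k2 = coupling**2
    return k2 / np.sqrt(k2 + (1.0 - k2) / n_seed_voxels)


def simulate_normative_connectome(config: SimulationConfig) -> list[NormativeScan]:
    """Generate the synthetic normative resting-state cohort.

    Every scan has unit-variance voxel series (before demeaning); voxels in
    the seed or target regions share one latent time course per scan scaled
    by ``network_coupling``.  Series are stored time-major in float32.
    """
    if config.network_seed_region is None or config.network_target_regions is None:
        raise ValueError("network regions must be set to simulate a connectome")
    network = config.network_seed_region | config.network_target_regions
    if config.network_coupling > 0 and not config.network_target_regions.any():
        raise ValueError("target mask empty at nonzero coupling")
    kappa = config.network_coupling
    mix = np.sqrt(1.0 - kappa**2)
    scans = []
    for j in range(config.n_normative):
        rng = _subject_rng(config.rng_seed, _STREAM_CONNECTOME, j)
        latent = rng.standard_normal(config.n_timepoints)
        series = rng.standard_normal((config.n_timepoints,) + config.grid.shape)
        series[:, network] = kappa * latent[:, None] + mix * series[:, network]
        series -= series.mean(axis=0)
        scans.append(NormativeScan(
            subject_id=f"norm-{j:04d}", series=series.astype(np.float32), grid=config.grid
        ))
    return scans


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# Count-matched cohorts (worked-example arithmetic)
# ---------------------------------------------------------------------------

#: normative model whose prediction is 0 with residual SD 1: raw scores ARE z-scores
IDENTITY_NORMS = NormativeModel(
    coefficients={t: (0.0, 0.0, 0.0, 0.0) for t in TESTS},
    residual_sd={t: 1.0 for t in TESTS},
)


def count_matched_cohort(
    n_total: int,
    n_impaired: int,
    impaired_domain_counts: dict[str, int],
    preserved_domain_counts: dict[str, int],
    n_mfis_available: int,
    n_fatigued: int,
    n_madrs_available: int,
    n_depressed: int,
) -> list[SubjectRecord]:
    """Deterministic cohort realising exact stratification counts.

    Builds ``n_total`` records whose raw scores are z-scores directly (score
    against :data:`IDENTITY_NORMS`): ``n_impaired`` subjects fail two or more
    domains with per-domain totals ``impaired_domain_counts``; preserved
    subjects with a single impaired domain realise
    ``preserved_domain_counts``; MFIS/MADRS presence and exceedance counts
    are laid out exactly.  Useful to check the classifier's prevalence
    arithmetic against published count tables.
    """
    domains = list(DOMAINS)
    imp = {d: int(impaired_domain_counts.get(d, 0)) for d in domains}
    pres = {d: int(preserved_domain_counts.get(d, 0)) for d in domains}
    total_flags = sum(imp.values())
    if n_impaired > 0 and not (2 * n_impaired <= total_flags <= 4 * n_impaired):
        raise ValueError("impaired domain counts need between 2 and 4 flags per subject")
    if max(imp.values(), default=0) > n_impaired:
        raise ValueError("a domain count exceeds the number of impaired subjects")
    n_single = sum(pres.values())
    if n_impaired + n_single > n_total:
        raise ValueError("counts exceed the cohort size")

    # impaired-domain patterns: rows with 3 flags first, each row taking the
    # domains with the largest remaining counts (Gale-Ryser style greedy)
    surplus = total_flags - 2 * n_impaired  # flags beyond the 2-per-row minimum
    n_quad = max(surplus - n_impaired, 0)
    n_triple = surplus - 2 * n_quad
    row_sizes = [4] * n_quad + [3] * n_triple + [2] * (n_impaired - n_quad - n_triple)
    patterns: list[tuple[str, ...]] = []
    remaining = dict(imp)
    for k in row_sizes:
        choose = sorted(domains, key=lambda d: -remaining[d])[:k]
        if remaining[choose[-1]] <= 0:
            raise ValueError("impaired domain counts are not realisable")
        for d in choose:
            remaining[d] -= 1
        patterns.append(tuple(choose))
    if any(remaining.values()):
        raise ValueError("impaired domain counts are not realisable")
    for d in domains:
        for _ in range(pres[d]):
            patterns.append((d,))
    patterns.extend(() for _ in range(n_total - len(patterns)))

    records = []
    for i, pat in enumerate(patterns):
        raw = {t: 0.0 for t in TESTS}
        for d in pat:
            raw[DOMAINS[d][0]] = -2.0  # fail the domain's first test
        mfis = None
        if i < n_mfis_available:
            mfis = 50.0 if i < n_fatigued else 10.0
        madrs = None
        if i < n_madrs_available:
            madrs = 20.0 if i < n_depressed else 5.0
        records.append(SubjectRecord(
            subject_id=f"case-{i:04d}", age=40.0, sex=i % 2, education=13.0,
            edss=2.0, scanner=1 + i % 2, raw_scores=raw, mfis=mfis, madrs=madrs,
        ))
    return records


#: generating normative regressions: raw = b0 + b_age*age + b_sex*sex + b_edu*edu,
#: residual SD 1 per test (so raw deviations are already on the z scale)
DEFAULT_TRUE_NORMS = NormativeModel(
    coefficients={t: (50.0, -0.20, 1.0, 0.50) for t in TESTS},
    residual_sd={t: 1.0 for t in TESTS},
)


def simulate_clinical_scores(
    masks: list[BinaryLesionMask],
    truth: GroundTruth,
    config: SimulationConfig,
    norms: NormativeModel = DEFAULT_TRUE_NORMS,
) -> list[SubjectRecord]:
    """Clinical records coupled to lesion load in the planted region.

    Raw test scores follow the generating normative regression minus
    ``score_effect`` residual-SD units per unit fractional lesion load in
    the effect region, plus unit-z noise.  Fatigue and depression scales
    are drawn so that configurable fractions exceed their cut-offs,
    independent of lesion load.  Demographics emulate a large adult MS
    cohort (age ~ N(44, 11.5), 59% women, education ~ N(13, 3.5), ordinal
    EDSS around 2.5, two scanners, ~36% progressive).
    """
    if len(masks) != len(truth.group_labels):
        raise ValueError("one mask per ground-truth subject required")
    region_size = max(int(truth.effect_region.sum()), 1)
    records = []
    for i, mask in enumerate(masks):
        rng = _subject_rng(config.rng_seed, _STREAM_CLINICAL, i)
        age = float(np.clip(rng.normal(43.7, 11.5), 18.0, 80.0))
        sex = int(rng.random() < 0.59)
        education = float(np.clip(rng.normal(13.0, 3.5), 5.0, 22.0))
        edss = float(np.clip(np.round(rng.normal(3.0, 2.0) * 2.0) / 2.0, 0.0, 10.0))
        scanner = int(rng.random() < 0.49) + 1
        course = "progressive" if rng.random() < 0.36 else "RR"
        load_frac = truth.lesion_load[i] / region_size
        shift = config.score_effect * load_frac
        raw = {}
        for test in TESTS:
            pred = norms.predict(test, age, sex, education)
            sd = norms.residual_sd[test]
            raw[test] = pred + sd * (rng.standard_normal() - shift)
        mfis = None
        if rng.random() >= config.missing_mfis_fraction:
            mfis = float(np.clip(np.round(rng.normal(config.mfis_mean, config.mfis_sd)), 0, 84))
        madrs = None
        if rng.random() >= config.missing_madrs_fraction:
            madrs = float(np.clip(np.round(rng.normal(config.madrs_mean, config.madrs_sd)), 0, 60))
        records.append(SubjectRecord(
            subject_id=mask.subject_id,
            age=age,
            sex=sex,
            education=education,
            edss=edss,
            scanner=scanner,
            course=course,
            raw_scores=raw,
            mfis=mfis,
            madrs=madrs,
            t2lv=mask.lesion_volume_ml(),
        ))
    truth.score_model = norms
    return records
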