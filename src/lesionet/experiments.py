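"""End-to-end validation studies on synthetic ground truth.

These drive the whole pipeline under planted conditions and measure what a
user of the package most needs to trust:

* worked-example prevalence arithmetic of the cohort classifier on a
  count-matched cohort;
* type-I error calibration of the permutation engine on exchangeable null
  simulations;
* recovery of a planted lesion-frequency excess (lesion probability
  mapping) and of a planted functional network (lesion network mapping),
  scored by Dice overlap between the significant clusters and the truth;
* the scanner-split map-similarity analysis (Dice / MSE between lesion
  probability maps of two half-cohorts).

Both the test suite and ``scripts/acceptance.py`` call these functions, so
the numbers they report are always produced by running the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from . import synthetic
from .cohort import score_and_classify, stratify_cohort
from .inference import DesignMatrix, InferenceSettings, permutation_inference
from .lnm import compare_lnm_groups, compute_lnms
from .lpm import compare_lesion_probability, compute_lpm
from .similarity import dice_coefficient, mean_square_error

__all__ = [
    "prevalence_worked_example",
    "null_calibration",
    "lpm_recovery",
    "lnm_recovery",
    "scanner_split_similarity",
    "dice_overlap",
]

#: published count table this package uses as its worked example: per-domain
#: impairment counts among impaired / preserved patients, instrument
#: availability and positives, in a 596-patient cohort
WORKED_EXAMPLE_COUNTS = {
    "n_total": 596,
    "n_impaired": 162,
    "impaired_domain_counts": {
        "processing_speed_attention": 131,
        "verbal_memory": 126,
        "visual_memory": 88,
        "verbal_fluency": 74,
    },
    "preserved_domain_counts": {
        "processing_speed_attention": 81,
        "verbal_memory": 54,
        "visual_memory": 14,
        "verbal_fluency": 23,
    },
    "n_mfis_available": 493,
    "n_fatigued": 184,
    "n_madrs_available": 495,
    "n_depressed": 192,
}


def dice_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Plain Dice between two boolean volumes (0 when both empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def prevalence_worked_example(counts: dict | None = None) -> dict:
    """Classify a count-matched cohort and report every split's prevalence.

    The counts (default: the package's worked example) are *inputs*; the
    prevalences come out of the actual scoring -> classification ->
    stratification path.
    """
    counts = dict(counts or WORKED_EXAMPLE_COUNTS)
    records = synthetic.count_matched_cohort(**counts)
    profiles = [score_and_classify(r, synthetic.IDENTITY_NORMS) for r in records]
    report = stratify_cohort(profiles)
    out = {}
    for name, split in report.splits.items():
        out[name] = {
            "n_positive": split.n_positive,
            "n_total": split.n_total,
            "prevalence_pct": split.prevalence,
        }
    return out


def _nuisance_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.normal(43.7, 11.5, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "edss": np.clip(rng.normal(3.0, 2.0, n), 0, 10),
        "scanner": rng.integers(1, 3, n).astype(float),
    })


def null_calibration(
    n_simulations: int = 200,
    n_subjects: int = 40,
    n_permutations: int = 250,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Familywise false-positive rates on exchangeable null simulations.

    Each simulation draws spatially smooth Gaussian subject volumes (no
    group effect anywhere), splits them half/half, and runs the full
    covariate-adjusted permutation GLM.  Smooth continuous data give the
    cluster-extent null enough resolution to measure the rate; the
    cluster-forming threshold is relaxed to p < 0.01 with no extent floor
    for the same reason.  Reported rates are for the positive contrast, the
    familywise level the engine claims per contrast.
    """
    phantom = synthetic.default_phantom()
    mask = phantom.wm_probability > 0.25
    vox_hits = clu_hits = 0
    for rep in range(n_simulations):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10, rep)))
        data = np.stack([
            ndimage.gaussian_filter(rng.standard_normal(phantom.grid.shape), 1.5)
            for _ in range(n_subjects)
        ])
        group = np.zeros(n_subjects)
        group[n_subjects // 2:] = 1
        design = DesignMatrix.two_group(group, _nuisance_frame(rng, n_subjects))
        settings = InferenceSettings(n_permutations=n_permutations, cluster_forming_p=0.01,
                                     k_e_min=1, alpha=alpha, rng_seed=rep)
        result = permutation_inference(data, design, settings, phantom.grid, mask)
        statmap, clusters = result.pos
        vox_hits += bool((statmap.p_fwe_voxel[mask] <= alpha).any())
        clu_hits += bool(len(clusters.significant(alpha)) > 0)
    return {
        "n_simulations": n_simulations,
        "voxel_fwe_fpr": vox_hits / n_simulations,
        "cluster_fwe_fpr": clu_hits / n_simulations,
    }


def lpm_recovery(
    n_replicates: int = 20,
    n_per_group: int = 100,
    effect_delta: float = 0.4,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Recovery of a planted lesion-frequency excess by the LPM comparison.

    Group B carries ``effect_delta`` extra lesion probability inside the
    phantom's effect region; recovery is the Dice overlap between the
    cluster-FWE-significant voxels (B > A) and the planted region.
    """
    phantom = synthetic.default_phantom()
    dices = []
    for rep in range(n_replicates):
        cfg = synthetic.default_config(
            n_per_group=(n_per_group, n_per_group), effect_delta=effect_delta,
            rng_seed=int(np.random.SeedSequence(seed, spawn_key=(20, rep)).generate_state(1)[0] % 2**31),
        )
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21, rep)))
        settings = InferenceSettings(n_permutations=n_permutations, cluster_forming_p=0.001,
                                     k_e_min=10, alpha=alpha, rng_seed=rep)
        result = compare_lesion_probability(
            masks[:n_per_group], masks[n_per_group:],
            _nuisance_frame(rng, 2 * n_per_group),
            phantom.wm_probability, settings,
        )
        sig = result.pos[1].significant_mask(alpha)
        dices.append(dice_overlap(sig, truth.effect_region))
    dices = np.asarray(dices)
    return {
        "n_replicates": n_replicates,
        "dice": dices,
        "mean_dice": float(dices.mean()),
        "fraction_recovered": float((dices >= 0.5).mean()),
    }


def lnm_recovery(
    n_replicates: int = 10,
    n_per_group: int = 50,
    coupling: float = 0.8,
    n_normative: int = 50,
    n_timepoints: int = 60,
    seed_delta: float = 0.2,
    n_permutations: int = 250,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Recovery of a planted functional network by the LNM comparison.

    Both groups draw lesions from the same background field; group B gets
    ``seed_delta`` extra lesion probability inside the network's seed
    region.  Because group B's lesions are better connected to the latent
    network, their lesion network maps should differ from group A's inside
    the target regions — recovery is the Dice overlap between the
    cluster-FWE-significant voxels (B > A, within gray matter) and the true
    target mask.
    """
    phantom = synthetic.default_phantom()
    dices = []
    for rep in range(n_replicates):
        root = int(np.random.SeedSequence(seed, spawn_key=(30, rep)).generate_state(1)[0] % 2**31)
        cfg = synthetic.default_config(
            n_per_group=(n_per_group, n_per_group), network_coupling=coupling,
            n_normative=n_normative, n_timepoints=n_timepoints, rng_seed=root,
        ).with_(effect_region=phantom.network_seed_region, effect_delta=seed_delta)
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        scans = synthetic.simulate_normative_connectome(cfg)
        lnms = compute_lnms(masks, scans)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(31, rep)))
        covars = _nuisance_frame(rng, 2 * n_per_group)
        covars["t2lv"] = [max(m.lesion_volume_ml(), 1e-3) for m in masks]
        settings = InferenceSettings(n_permutations=n_permutations, cluster_forming_p=0.001,
                                     k_e_min=10, alpha=alpha, rng_seed=rep)
        result = compare_lnm_groups(
            lnms[:n_per_group], lnms[n_per_group:], covars,
            phantom.gm_probability, settings,
        )
        sig = result.pos[1].significant_mask(alpha)
        dices.append(dice_overlap(sig, truth.target_mask))
    dices = np.asarray(dices)
    return {
        "n_replicates": n_replicates,
        "dice": dices,
        "mean_dice": float(dices.mean()),
        "fraction_recovered": float((dices >= 0.5).mean()),
    }


def scanner_split_similarity(
    n_per_scanner: int = 150, base_rate: float = 0.10, seed: int = 0
) -> dict:
    """Dice and MSE between lesion probability maps of two scanner halves.

    Emulates the validation analysis: one cohort, split by (synthetic)
    scanner, LPM per half, agreement quantified.  With both halves drawn
    from the same lesion model the maps should overlap strongly.
    """
    cfg = synthetic.default_config(
        n_per_group=(n_per_scanner, n_per_scanner), effect_delta=0.0,
        rng_seed=int(np.random.SeedSequence(seed, spawn_key=(40,)).generate_state(1)[0] % 2**31),
    )
    masks, _ = synthetic.simulate_lesion_cohort(cfg)
    lpm_1 = compute_lpm(masks[:n_per_scanner], group="scanner1")
    lpm_2 = compute_lpm(masks[n_per_scanner:], group="scanner2")
    return {
        "dice": dice_coefficient(lpm_1, lpm_2, threshold=0.0),
        "mse": mean_square_error(lpm_1, lpm_2),
        "n_per_scanner": n_per_scanner,
    }
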