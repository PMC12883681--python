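"""Generator contracts: determinism, exact marginal laws, closed-form network correlations."""

import numpy as np
import pytest
from scipy import stats

from lesionet import synthetic
from lesionet.cohort import TESTS


def _cfg(**kw):
    return synthetic.default_config(**kw)


class TestLesionCohort:
    def test_masks_are_binary_and_on_grid(self):
        masks, truth = synthetic.simulate_lesion_cohort(_cfg(n_per_group=(3, 3), rng_seed=1))
        assert len(masks) == 6
        for m in masks:
            assert set(np.unique(m.volume)).issubset({0, 1})
            assert m.volume.shape == m.grid.shape

    def test_determinism_bit_identical(self):
        cfg = _cfg(n_per_group=(4, 4), effect_delta=0.3, rng_seed=7)
        a, _ = synthetic.simulate_lesion_cohort(cfg)
        b, _ = synthetic.simulate_lesion_cohort(cfg)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.volume, mb.volume)

    def test_null_configuration_no_group_difference(self):
        """With effect_delta 0 both groups share one lesion model."""
        cfg = _cfg(n_per_group=(100, 100), effect_delta=0.0, rng_seed=3)
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        stack = np.stack([m.volume for m in masks]).astype(float)
        region = cfg.effect_region
        fa = stack[truth.group_labels == 0][:, region].mean()
        fb = stack[truth.group_labels == 1][:, region].mean()
        n_vox = int(region.sum())
        se = np.sqrt(2 * 0.1 * 0.9 / (100 * n_vox))  # ignores spatial correlation: bound only
        assert abs(fa - fb) < 6 * se

    def test_marginal_law_matches_binomial(self):
        """Per-voxel lesion frequency matches its generating probability.

        Exact binomial tests at alpha=0.001 on voxels spaced > 2 FWHM apart
        (spatial smoothing correlates neighbours but leaves the marginal law
        exact, so well-separated voxels are effectively independent draws).
        """
        cfg = _cfg(n_per_group=(200, 200), effect_delta=0.4, rng_seed=11)
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        stack = np.stack([m.volume for m in masks])
        a = stack[truth.group_labels == 0]
        b = stack[truth.group_labels == 1]
        region = cfg.effect_region
        wm = cfg.base_lesion_field > 0
        # base-rate voxels in group A, on a coarse lattice
        lattice = np.zeros(cfg.grid.shape, bool)
        lattice[::7, ::7, ::7] = True
        for idx in np.argwhere(wm & lattice & ~region):
            k = int(a[(slice(None),) + tuple(idx)].sum())
            assert stats.binomtest(k, 200, 0.1).pvalue > 0.001
        # elevated voxels in group B: region center (regions are small, test one)
        center = tuple(np.argwhere(region)[len(np.argwhere(region)) // 2])
        k = int(b[(slice(None),) + center].sum())
        assert stats.binomtest(k, 200, 0.5).pvalue > 0.001

    def test_zero_base_half_delta(self):
        """base 0 everywhere + delta 0.5 in region: group B frequency ~ 0.5, A exactly 0."""
        phantom = synthetic.default_phantom(base_rate=0.0)
        cfg = synthetic.default_config(n_per_group=(200, 200), rng_seed=5).with_(
            base_lesion_field=phantom.base_lesion_field, effect_delta=0.5
        )
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        stack = np.stack([m.volume for m in masks]).astype(float)
        a = stack[truth.group_labels == 0]
        b = stack[truth.group_labels == 1]
        assert a.sum() == 0
        region = cfg.effect_region
        freq = b[:, region].mean()
        se = np.sqrt(0.25 / 200)  # per-voxel binomial SE at n=200
        assert abs(freq - 0.5) < 3 * se
        assert b[:, ~region].sum() == 0

    def test_lesions_are_blobs_not_salt_and_pepper(self):
        masks, _ = synthetic.simulate_lesion_cohort(_cfg(n_per_group=(5, 5), rng_seed=2))
        from scipy import ndimage

        sizes = []
        for m in masks:
            if m.is_empty:
                continue
            lab, n = ndimage.label(m.volume)
            sizes.extend(np.bincount(lab.ravel())[1:].tolist())
        assert np.mean(sizes) > 2.0  # smoothed fields give multi-voxel components

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            _cfg(effect_delta=0.95)


class TestNormativeConnectome:
    def test_null_coupling_zero_correlation(self):
        cfg = _cfg(n_per_group=(2, 2), network_coupling=0.0, n_normative=30,
                   n_timepoints=120, rng_seed=4)
        scans = synthetic.simulate_normative_connectome(cfg)
        seed = cfg.network_seed_region
        target_idx = tuple(np.argwhere(cfg.network_target_regions)[0])
        rs = []
        for s in scans:
            tc = s.series[:, seed].mean(axis=1).astype(float)
            v = s.series[(slice(None),) + target_idx].astype(float)
            rs.append(np.corrcoef(tc, v)[0, 1])
        se = 1 / np.sqrt((120 - 3) * len(rs))
        assert abs(np.mean(rs)) < 3 * se

    def test_pairwise_network_correlation_closed_form(self):
        """Two network voxels correlate at coupling^2 under the latent model."""
        cfg = _cfg(n_per_group=(2, 2), network_coupling=0.9, n_normative=40,
                   n_timepoints=200, rng_seed=9)
        scans = synthetic.simulate_normative_connectome(cfg)
        i1 = tuple(np.argwhere(cfg.network_seed_region)[0])
        i2 = tuple(np.argwhere(cfg.network_target_regions)[-1])
        rs = [
            np.corrcoef(s.series[(slice(None),) + i1].astype(float),
                        s.series[(slice(None),) + i2].astype(float))[0, 1]
            for s in scans
        ]
        expected = synthetic.expected_pairwise_network_r(0.9)
        se = (1 - expected**2) / np.sqrt((200 - 3) * len(rs))
        assert abs(np.mean(rs) - expected) < 3.5 * se

    def test_seed_mean_target_correlation_closed_form(self):
        cfg = _cfg(n_per_group=(2, 2), network_coupling=0.9, n_normative=40,
                   n_timepoints=200, rng_seed=13)
        scans = synthetic.simulate_normative_connectome(cfg)
        seed = cfg.network_seed_region
        tgt = tuple(np.argwhere(cfg.network_target_regions)[0])
        rs = [
            np.corrcoef(s.series[:, seed].mean(axis=1).astype(float),
                        s.series[(slice(None),) + tgt].astype(float))[0, 1]
            for s in scans
        ]
        expected = synthetic.expected_seed_mean_target_r(0.9, int(seed.sum()))
        se = (1 - expected**2) / np.sqrt((200 - 3) * len(rs))
        assert abs(np.mean(rs) - expected) < 3.5 * se

    def test_outside_network_uncorrelated(self):
        cfg = _cfg(n_per_group=(2, 2), network_coupling=0.9, n_normative=30,
                   n_timepoints=120, rng_seed=6)
        scans = synthetic.simulate_normative_connectome(cfg)
        outside = ~(cfg.network_seed_region | cfg.network_target_regions)
        v1, v2 = [tuple(i) for i in np.argwhere(outside)[:2]]
        rs = [
            np.corrcoef(s.series[(slice(None),) + v1].astype(float),
                        s.series[(slice(None),) + v2].astype(float))[0, 1]
            for s in scans
        ]
        assert abs(np.mean(rs)) < 3 / np.sqrt((120 - 3) * len(rs))

    def test_zero_temporal_mean(self):
        cfg = _cfg(n_per_group=(2, 2), network_coupling=0.5, n_normative=2,
                   n_timepoints=16, rng_seed=8)
        scans = synthetic.simulate_normative_connectome(cfg)
        assert np.abs(scans[0].series.mean(axis=0)).max() < 1e-5

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            _cfg(n_timepoints=7)


class TestClinicalScores:
    def test_null_coupling_prevalence_balanced(self):
        cfg = _cfg(n_per_group=(150, 150), effect_delta=0.4, score_effect=0.0, rng_seed=21)
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        records = synthetic.simulate_clinical_scores(masks, truth, cfg)
        za = [r.raw_scores["sdmt"] for r, g in zip(records, truth.group_labels) if g == 0]
        zb = [r.raw_scores["sdmt"] for r, g in zip(records, truth.group_labels) if g == 1]
        # same score model in both groups: two-sample t should be unremarkable
        t, p = stats.ttest_ind(za, zb)
        assert p > 0.001

    def test_strong_coupling_drives_failures(self):
        """Large deficit per unit load: loaded subjects fail with probability -> 1."""
        cfg = _cfg(n_per_group=(60, 60), effect_delta=0.6, score_effect=8.0, rng_seed=22)
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        records = synthetic.simulate_clinical_scores(masks, truth, cfg)
        model = synthetic.DEFAULT_TRUE_NORMS
        region = int(truth.effect_region.sum())
        loaded = [
            r for r, load in zip(records, truth.lesion_load) if load > 0.5 * region
        ]
        assert len(loaded) > 10
        # z-shift for load > region/2 is > 4 SD: failure of every test is near-certain
        n_fail = sum(
            all(model.zscore(t_, r.raw_scores[t_], r.age, r.sex, r.education) <= -1.5
                for t_ in TESTS)
            for r in loaded
        )
        assert n_fail / len(loaded) > 0.9

    def test_fixed_seed_reproducible(self):
        cfg = _cfg(n_per_group=(5, 5), rng_seed=33)
        masks, truth = synthetic.simulate_lesion_cohort(cfg)
        r1 = synthetic.simulate_clinical_scores(masks, truth, cfg)
        r2 = synthetic.simulate_clinical_scores(masks, truth, cfg)
        for a, b in zip(r1, r2):
            assert a == b


class TestCountMatchedCohort:
    def test_counts_round_trip_through_classifier(self):
        from lesionet.cohort import score_and_classify, stratify_cohort

        records = synthetic.count_matched_cohort(
            n_total=10, n_impaired=3,
            impaired_domain_counts={"verbal_memory": 3, "visual_memory": 2,
                                    "processing_speed_attention": 2, "verbal_fluency": 0},
            preserved_domain_counts={"verbal_fluency": 2},
            n_mfis_available=8, n_fatigued=4, n_madrs_available=6, n_depressed=2,
        )
        profiles = [score_and_classify(r, synthetic.IDENTITY_NORMS) for r in records]
        report = stratify_cohort(profiles)
        assert report.splits["cognitive_impairment"].n_positive == 3
        assert report.splits["verbal_memory"].n_positive == 3
        assert report.splits["verbal_fluency"].n_positive == 2
        assert report.splits["fatigue"].n_positive == 4
        assert report.splits["fatigue"].n_total == 8
        assert report.splits["depression"].n_positive == 2
        assert report.splits["depression"].n_total == 6

    def test_unrealisable_counts_rejected(self):
        with pytest.raises(ValueError):
            synthetic.count_matched_cohort(
                n_total=10, n_impaired=2,
                impaired_domain_counts={"verbal_memory": 5},
                preserved_domain_counts={},
                n_mfis_available=0, n_fatigued=0, n_madrs_available=0, n_depressed=0,
            )
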