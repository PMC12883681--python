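"""GLM t oracles, exhaustive permutation equivalence, FWE bookkeeping, clustering."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lesionet.grid import VolumeGrid
from lesionet.inference import (
    DesignMatrix,
    InferenceSettings,
    RankDeficientDesignError,
    extract_clusters,
    glm_tmap,
    permutation_inference,
)


def _two_sample_t_textbook(a, b):
    """Independent pooled-variance two-sample t (direct formula)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestGlmTmap:
    def test_matches_two_sample_t_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        design = DesignMatrix.two_group(np.array([0, 0, 0, 1, 1, 1]))
        t, deg = glm_tmap(np.array(a + b)[:, None], design)
        assert t[0] == pytest.approx(_two_sample_t_textbook(a, b), abs=1e-10)
        assert t[0] == pytest.approx(3 * math.sqrt(1.5), abs=1e-10)
        assert not deg[0]

    def test_matches_statsmodels_with_covariates(self, rng):
        """Independent cross-check of the covariate-adjusted contrast t."""
        import statsmodels.api as sm

        n = 25
        X = np.column_stack([
            rng.integers(0, 2, n).astype(float),
            rng.normal(40, 10, n),
            np.ones(n),
        ])
        y = rng.standard_normal(n)
        design = DesignMatrix(X, ("group", "age", "intercept"), np.array([1.0, 0.0, 0.0]))
        t, _ = glm_tmap(y[:, None], design)
        fit = sm.OLS(y, X).fit()
        assert t[0] == pytest.approx(fit.tvalues[0], abs=1e-10)

    def test_degenerate_voxel_flagged(self):
        design = DesignMatrix.two_group(np.array([0, 0, 0, 1, 1, 1]))
        t, deg = glm_tmap(np.full((6, 1), 3.14), design)
        assert deg[0] and t[0] == 0.0

    def test_rank_deficiency_named(self):
        X = np.column_stack([np.array([0, 0, 1, 1.0]), np.ones(4), np.ones(4)])
        with pytest.raises(RankDeficientDesignError):
            DesignMatrix(X, ("group", "ones", "intercept"), np.array([1.0, 0, 0]))

    def test_covariate_rescaling_invariance(self, rng):
        n = 20
        age = rng.normal(40, 10, n)
        group = (np.arange(n) >= 10).astype(float)
        y = rng.standard_normal((n, 5))
        import pandas as pd

        d1 = DesignMatrix.two_group(group, pd.DataFrame({"age": age}))
        d2 = DesignMatrix.two_group(group, pd.DataFrame({"age": 3.7 * age + 11.0}))
        t1, _ = glm_tmap(y, d1)
        t2, _ = glm_tmap(y, d2)
        assert np.allclose(t1, t2, atol=1e-10)

    def test_label_swap_negates_t(self, rng):
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        y = rng.standard_normal((8, 7))
        t_fwd, _ = glm_tmap(y, DesignMatrix.two_group(group))
        t_rev, _ = glm_tmap(y, DesignMatrix.two_group(1 - group))
        assert np.allclose(t_fwd, -t_rev, atol=1e-10)


def _brute_force_split_p(y, n_a, t_obs):
    """Exhaustive one-sided permutation p over all group splits."""
    n = len(y)
    vals = []
    for subset in itertools.combinations(range(n), n - n_a):
        g = np.zeros(n)
        g[list(subset)] = 1
        t, _ = glm_tmap(np.asarray(y, float)[:, None], DesignMatrix.two_group(g))
        vals.append(t[0])
    return np.mean([v >= t_obs for v in vals])


class TestPermutationInference:
    def _run_single_voxel(self, y, n_a, n_perm=100, seed=0):
        grid = VolumeGrid.isotropic((1, 1, 1))
        mask = np.ones((1, 1, 1), bool)
        group = np.zeros(len(y))
        group[n_a:] = 1
        design = DesignMatrix.two_group(group)
        settings = InferenceSettings(n_permutations=n_perm, cluster_forming_p=0.01,
                                     k_e_min=1, rng_seed=seed)
        return permutation_inference(np.asarray(y, float)[:, None], design, settings,
                                     grid, mask), design

    @pytest.mark.parametrize("y,n_a", [
        ([1.2, 0.3, -0.5, 2.5, 3.1, 2.0], 3),     # 3 vs 3: 20 splits
        ([0.1, 1.0, -2.0, 0.7, 2.2, 1.5, 0.9], 3),  # 3 vs 4: 35 splits
    ])
    def test_exhaustive_matches_brute_force_exactly(self, y, n_a):
        res, design = self._run_single_voxel(y, n_a)
        t_obs = res.pos[0].t[0, 0, 0]
        expected = _brute_force_split_p(y, n_a, t_obs)
        assert res.exhaustive
        assert res.pos[0].p_unc[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        # single voxel: the voxel-FWE p equals the uncorrected p
        assert res.pos[0].p_fwe_voxel[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_not_significant(self):
        """Byte-identical groups: t = 0 sits at the centre of its own null, so
        each one-sided p is ~0.5 and the two directions jointly cover the null."""
        res, _ = self._run_single_voxel([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], 3)
        p_pos = res.pos[0].p_unc[0, 0, 0]
        p_neg = res.neg[0].p_unc[0, 0, 0]
        assert p_pos >= 0.4 and p_neg >= 0.4
        assert p_pos + p_neg >= 0.9

    def test_all_identical_data_p_one(self):
        res, _ = self._run_single_voxel([5.0] * 6, 3)
        assert res.pos[0].p_unc[0, 0, 0] == 1.0
        assert res.pos[0].p_fwe_voxel[0, 0, 0] == 1.0

    def test_default_settings_five_thousand_permutations(self):
        assert InferenceSettings().n_permutations == 5000
        assert InferenceSettings().cluster_forming_p == 0.001
        assert InferenceSettings().k_e_min == 50

    def test_corrected_never_below_uncorrected(self, rng):
        grid = VolumeGrid.isotropic((4, 4, 4))
        mask = np.ones(grid.shape, bool)
        y = rng.standard_normal((12, 64))
        group = np.zeros(12)
        group[6:] = 1
        design = DesignMatrix.two_group(group)
        settings = InferenceSettings(n_permutations=200, cluster_forming_p=0.01,
                                     k_e_min=1, rng_seed=1)
        res = permutation_inference(y, design, settings, grid, mask)
        for sm, _ in (res.pos, res.neg):
            assert np.all(sm.p_fwe_voxel[mask] >= sm.p_unc[mask] - 1e-12)
            assert np.all(sm.p_unc[mask] > 0)
            assert np.all(sm.p_fwe_voxel[mask] <= 1)

    def test_deterministic_given_seed(self, rng):
        grid = VolumeGrid.isotropic((3, 3, 3))
        mask = np.ones(grid.shape, bool)
        y = rng.standard_normal((14, 27))
        group = np.zeros(14)
        group[7:] = 1
        design = DesignMatrix.two_group(group)
        settings = InferenceSettings(n_permutations=150, cluster_forming_p=0.01,
                                     k_e_min=1, rng_seed=42)
        r1 = permutation_inference(y, design, settings, grid, mask)
        r2 = permutation_inference(y, design, settings, grid, mask)
        assert np.array_equal(r1.pos[0].p_unc, r2.pos[0].p_unc)
        assert np.array_equal(r1.pos[0].p_fwe_voxel, r2.pos[0].p_fwe_voxel)

    def test_freedman_lane_used_with_covariates(self, rng):
        """With continuous nuisance the engine samples permutations (not exhaustive)."""
        import pandas as pd

        grid = VolumeGrid.isotropic((2, 2, 2))
        mask = np.ones(grid.shape, bool)
        y = rng.standard_normal((6, 8))
        group = np.array([0, 0, 0, 1, 1, 1.0])
        design = DesignMatrix.two_group(group, pd.DataFrame({"age": rng.normal(40, 5, 6)}))
        settings = InferenceSettings(n_permutations=100, cluster_forming_p=0.01,
                                     k_e_min=1, rng_seed=0)
        res = permutation_inference(y, design, settings, grid, mask)
        assert not res.exhaustive
        assert res.n_permutations_used == 100


class TestClusterExtraction:
    def _settings(self, conn, k=1):
        return InferenceSettings(n_permutations=100, cluster_forming_p=0.01,
                                 k_e_min=k, connectivity=conn)

    def test_corner_adjacency_depends_on_connectivity(self):
        grid = VolumeGrid.isotropic((3, 3, 3))
        mask = np.ones(grid.shape, bool)
        t = np.zeros(grid.shape)
        t[0, 0, 0] = 5.0
        t[1, 1, 1] = 5.0  # shares only a corner with (0,0,0)
        c26 = extract_clusters(t, mask, 3.0, self._settings(26), grid)
        c6 = extract_clusters(t, mask, 3.0, self._settings(6), grid)
        assert len(c26.table) == 1
        assert len(c6.table) == 2

    def test_edge_adjacency_at_18(self):
        grid = VolumeGrid.isotropic((3, 3, 3))
        mask = np.ones(grid.shape, bool)
        t = np.zeros(grid.shape)
        t[0, 0, 0] = 5.0
        t[0, 1, 1] = 5.0  # shares an edge
        c18 = extract_clusters(t, mask, 3.0, self._settings(18), grid)
        assert len(c18.table) == 1

    def test_extent_floor_drops_small_clusters(self):
        grid = VolumeGrid.isotropic((10, 10, 10))
        mask = np.ones(grid.shape, bool)
        t = np.zeros(grid.shape)
        t[:7, :7, 0] = 5.0  # 49-voxel slab
        ct = extract_clusters(t, mask, 3.0, InferenceSettings(k_e_min=50), grid)
        assert len(ct.table) == 0
        ct2 = extract_clusters(t, mask, 3.0, InferenceSettings(k_e_min=49), grid)
        assert len(ct2.table) == 1
        assert ct2.table.iloc[0]["extent"] == 49

    def test_peak_reported_in_world_mm(self):
        grid = VolumeGrid.isotropic((5, 5, 5), voxel_mm=2.0)
        mask = np.ones(grid.shape, bool)
        t = np.zeros(grid.shape)
        t[4, 4, 4] = 6.0
        ct = extract_clusters(t, mask, 3.0, self._settings(18), grid)
        row = ct.table.iloc[0]
        expected = grid.voxel_to_world(np.array([4, 4, 4]))
        assert (row["peak_x"], row["peak_y"], row["peak_z"]) == tuple(expected)

    def test_cluster_labels_from_atlas(self):
        from lesionet.io_atlas import AtlasVolume

        grid = VolumeGrid.isotropic((6, 6, 6))
        mask = np.ones(grid.shape, bool)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[:3] = 1
        labels[3:] = 2
        atlas = AtlasVolume(labels=labels, names={1: "anterior", 2: "posterior"}, grid=grid)
        t = np.zeros(grid.shape)
        t[2:4, 0, 0] = 5.0  # straddles both regions 50/50
        ct = extract_clusters(t, mask, 3.0, self._settings(18), grid, atlas=atlas)
        assert "anterior (50%)" in ct.table.iloc[0]["labels"]
        assert "posterior (50%)" in ct.table.iloc[0]["labels"]


class TestSettingsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"cluster_forming_p": 0.2, "alpha": 0.05},
        {"n_permutations": 50},
        {"connectivity": 10},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InferenceSettings(**kwargs)

    def test_cluster_forming_threshold_uses_student_df(self):
        # threshold used for clustering equals the t quantile at residual df
        df = 34
        assert stats.t.isf(0.001, df) == pytest.approx(3.348, abs=5e-3)
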