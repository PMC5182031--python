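"""Fixel-wise GLM and max-statistic permutation FWE inference."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from fixel.stats import (DesignMatrix, fit_glm, make_synthetic_cohort,
                         analyse_cohort, permutation_fwe)
from conftest import random_fixel_grid


class TestDesignMatrix:
    def test_rank_deficient_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError):
            DesignMatrix(X, [1.0, 0.0])

    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError):
            DesignMatrix(np.column_stack([np.arange(6.0), np.ones(6)]),
                         [0.0, 0.0])


class TestFitGLM:
    def test_equal_group_means_zero_noise(self):
        des = DesignMatrix.two_group(3, 3)
        Y = np.tile([[2.0], [2.0], [2.0], [2.0], [2.0], [2.0]], (1, 4))
        np.testing.assert_allclose(fit_glm(Y, des), 0.0, atol=1e-10)

    def test_matches_classical_two_sample_t(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        des = DesignMatrix.two_group(3, 3)
        t = fit_glm(np.array(a + b)[:, None], des)[0]
        assert t == pytest.approx(-3.674234614, abs=1e-8)
        assert t == pytest.approx(scipy_stats.ttest_ind(a, b).statistic,
                                  abs=1e-10)

    def test_orthogonal_nuisance_projection_property(self, rng):
        n = 12
        g = np.concatenate([np.ones(6), np.zeros(6)])
        Y = rng.normal(size=(n, 5))
        base = DesignMatrix(np.column_stack([g, np.ones(n)]), [1.0, 0.0])
        t0 = fit_glm(Y, base)
        # nuisance orthogonal to both group and data columns: the contrast
        # estimate and residuals are untouched, so t changes only through
        # the residual degrees of freedom (n-2 -> n-3)
        z = rng.normal(size=n)
        M = np.column_stack([g, np.ones(n), Y])
        z = z - M @ np.linalg.lstsq(M, z, rcond=None)[0]
        aug = DesignMatrix(np.column_stack([g, np.ones(n), z]),
                           [1.0, 0.0, 0.0])
        np.testing.assert_allclose(
            fit_glm(Y, aug), t0 * np.sqrt((n - 3) / (n - 2)), atol=1e-10)

    def test_nan_rejected(self):
        des = DesignMatrix.two_group(3, 3)
        Y = np.full((6, 2), np.nan)
        with pytest.raises(ValueError):
            fit_glm(Y, des)


class TestPermutationFWE:
    def test_p_value_floor(self, rng):
        Y = rng.normal(size=(8, 10))
        Y[:4] += 50.0                        # enormous effect
        des = DesignMatrix.two_group(4, 4)
        res = permutation_fwe(Y, des, n_perm=200, seed=0)
        assert res.p_fwe.min() >= 1.0 / (res.n_perm + 1) - 1e-12
        assert res.p_fwe.max() <= 1.0

    def test_seed_determinism(self, rng):
        Y = rng.normal(size=(12, 40))
        des = DesignMatrix.two_group(6, 6)
        r1 = permutation_fwe(Y, des, n_perm=300, seed=7)
        r2 = permutation_fwe(Y, des, n_perm=300, seed=7)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)
        np.testing.assert_array_equal(r1.max_stat_dist, r2.max_stat_dist)
        r3 = permutation_fwe(Y, des, n_perm=300, seed=8)
        assert not np.array_equal(r3.max_stat_dist, r1.max_stat_dist)

    def test_exhaustive_enumeration_small_n(self, rng):
        Y = rng.normal(size=(5, 6))
        des = DesignMatrix.two_group(3, 2)
        res = permutation_fwe(Y, des, n_perm=500, seed=0)
        assert res.n_perm == 120             # 5! distinct row permutations

    def test_p_monotone_in_statistic(self, rng):
        Y = rng.normal(size=(16, 60))
        Y[:8, :5] += 2.0
        des = DesignMatrix.two_group(8, 8)
        res = permutation_fwe(Y, des, n_perm=300, seed=3)
        order = np.argsort(np.abs(res.t))
        p_sorted = res.p_fwe[order]
        assert np.all(np.diff(p_sorted) <= 1e-12)

    def test_power_large_effect(self, rng):
        detected = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            Y = r.normal(size=(20, 200))
            Y[:10, :10] += 3.0               # Cohen's d = 3 in 10 fixels
            des = DesignMatrix.two_group(10, 10)
            res = permutation_fwe(Y, des, n_perm=500, seed=seed)
            detected.append(int(res.sig_mask[:10].sum()))
        assert np.median(detected) >= 9

    def test_small_n_perm_warns(self, rng):
        Y = rng.normal(size=(10, 5))
        des = DesignMatrix.two_group(5, 5)
        with pytest.warns(UserWarning):
            permutation_fwe(Y, des, n_perm=50, seed=0)

    def test_enhancement_hook_is_used(self, rng):
        Y = rng.normal(size=(12, 30))
        des = DesignMatrix.two_group(6, 6)
        base = permutation_fwe(Y, des, n_perm=200, seed=1)
        doubled = permutation_fwe(Y, des, n_perm=200, seed=1,
                                  enhance=lambda t: 2.0 * np.abs(t))
        # a monotone statistic transform leaves the ranks, hence p, alone
        np.testing.assert_allclose(doubled.p_fwe, base.p_fwe)
        np.testing.assert_allclose(doubled.max_stat_dist,
                                   2.0 * base.max_stat_dist)


class TestSyntheticCohort:
    def test_no_noise_no_effect_identical(self, rng):
        tpl = random_fixel_grid(rng)
        ga, gb = make_synthetic_cohort(tpl, 3, effect=1.0, noise_sd=0.0,
                                       seed=0)
        for s in ga + gb:
            np.testing.assert_array_equal(s.values["fd"], tpl.values["fd"])

    def test_seed_determinism_and_variation(self, rng):
        tpl = random_fixel_grid(rng)
        a1, _ = make_synthetic_cohort(tpl, 2, noise_sd=0.2, seed=5)
        a2, _ = make_synthetic_cohort(tpl, 2, noise_sd=0.2, seed=5)
        a3, _ = make_synthetic_cohort(tpl, 2, noise_sd=0.2, seed=6)
        np.testing.assert_array_equal(a1[0].values["fd"], a2[0].values["fd"])
        assert not np.array_equal(a1[0].values["fd"], a3[0].values["fd"])

    def test_group_ratio_estimates_effect(self, rng):
        tpl = random_fixel_grid(rng, shape=(4, 4, 1))
        ga, gb = make_synthetic_cohort(tpl, 200, effect=0.7, noise_sd=0.1,
                                       seed=11)
        ma = np.mean([s.values["fd"] for s in ga], axis=0)
        mb = np.mean([s.values["fd"] for s in gb], axis=0)
        ratio = np.median(mb / ma)
        assert ratio == pytest.approx(0.7, rel=0.05)


class TestAnalyseCohort:
    def test_identical_subjects_nothing_significant(self, rng):
        tpl = random_fixel_grid(rng, shape=(4, 4, 1))
        ga, gb = make_synthetic_cohort(tpl, 5, effect=1.0, noise_sd=0.0,
                                       seed=0)
        des = DesignMatrix.two_group(5, 5)
        res = analyse_cohort("fd", ga + gb, tpl, des, n_perm=200, seed=0)
        assert not res.sig_mask.any()

    def test_mask_matches_alpha_rule(self, rng):
        tpl = random_fixel_grid(rng, shape=(4, 4, 1))
        ga, gb = make_synthetic_cohort(tpl, 8, effect=0.5, noise_sd=0.05,
                                       seed=2)
        des = DesignMatrix.two_group(8, 8)
        res = analyse_cohort("fd", ga + gb, tpl, des, n_perm=300, seed=2)
        np.testing.assert_array_equal(res.sig_mask, res.p_fwe < 0.05)
        np.testing.assert_array_equal(
            res.sig_mask, res.sig_mask_negative | res.sig_mask_positive)

    def test_planted_tract_recovered(self, rng):
        tpl = random_fixel_grid(rng, shape=(6, 6, 1), max_fixels=2)
        F = tpl.n_fixels
        tract = np.zeros(F, dtype=bool)
        tract[:max(4, F // 8)] = True
        ga, gb = make_synthetic_cohort(tpl, 12, effect=0.7, noise_sd=0.05,
                                       seed=3, effect_mask=tract)
        des = DesignMatrix.two_group(12, 12)
        res = analyse_cohort("fd", ga + gb, tpl, des, n_perm=400, seed=3)
        recovered = res.sig_mask[tract].mean()
        assert recovered >= 0.8
        # significant fixels confined to the planted tract
        assert not res.sig_mask[~tract].any()

    def test_missing_metric_names_subject(self, rng):
        tpl = random_fixel_grid(rng, shape=(3, 3, 1))
        ga, gb = make_synthetic_cohort(tpl, 3, seed=0)
        with pytest.raises(KeyError, match="subject 0"):
            analyse_cohort("fc", ga + gb, tpl,
                           DesignMatrix.two_group(3, 3), n_perm=100, seed=0)
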