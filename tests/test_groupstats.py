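"""Group inference: scalar-test oracles applied voxelwise, null calibration,
Monte-Carlo extent thresholds, and cluster extraction semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcdpipe.groupstats import (
    StatResult,
    extract_clusters,
    monte_carlo_extent_threshold,
    one_sample_t,
    one_way_anova,
    posthoc_t,
    regress_covariates_across_subjects,
)
from fcdpipe.images import FcdPipeError

MASK8 = np.ones((2, 2, 2), bool)


class TestResidualization:
    def test_perfect_fit_leaves_grand_mean(self, rng):
        age = rng.uniform(20, 70, 20)
        values = 2.0 * age
        out = regress_covariates_across_subjects(values, age[:, None])
        np.testing.assert_allclose(out, values.mean(), atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        cov = rng.standard_normal((15, 3))
        values = rng.standard_normal((15, 4))
        out = regress_covariates_across_subjects(values, cov)
        centered = out - out.mean(axis=0)
        np.testing.assert_allclose(centered.T @ (cov - cov.mean(0)), 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        cov = rng.standard_normal((12, 2))
        values = rng.standard_normal(12)
        out = regress_covariates_across_subjects(values, cov, keep_mean=False)
        design = np.column_stack([np.ones(12), cov - cov.mean(0)])
        beta = np.linalg.solve(design.T @ design, design.T @ values)
        np.testing.assert_allclose(out, values - design @ beta, atol=1e-10)

    def test_sex_labels_coded_numerically(self, rng):
        cov = pd.DataFrame({"age": rng.uniform(20, 70, 10),
                            "sex": ["M", "F"] * 5,
                            "education": rng.uniform(5, 20, 10)})
        out = regress_covariates_across_subjects(rng.standard_normal(10), cov)
        assert np.isfinite(out).all()

    def test_collinear_covariates_rejected(self, rng):
        age = rng.uniform(20, 70, 10)
        cov = np.column_stack([age, 2 * age])
        with pytest.raises(FcdPipeError, match="collinear"):
            regress_covariates_across_subjects(rng.standard_normal(10), cov)


class TestOneSampleT:
    def test_identical_constant_maps_degenerate(self):
        maps = np.full((4, 2, 2, 2), 3.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = one_sample_t(maps, MASK8)
        assert np.all(np.isinf(res.stat_map[MASK8]))
        assert np.all(res.voxel_p_map[MASK8] == 0)

    def test_antisymmetric_values_give_t_zero(self):
        maps = np.stack([np.full((2, 2, 2), v) for v in (-2.0, -1.0, 1.0, 2.0)])
        res = one_sample_t(maps, MASK8)
        np.testing.assert_allclose(res.stat_map[MASK8], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.voxel_p_map[MASK8], 1.0, atol=1e-12)

    def test_matches_scipy_voxelwise(self, rng):
        maps = rng.standard_normal((5, 2, 2, 2))
        res = one_sample_t(maps, MASK8)
        t_ref, p_ref = stats.ttest_1samp(maps.reshape(5, -1), 0.0, axis=0)
        np.testing.assert_allclose(res.stat_map.ravel(), t_ref, atol=1e-10)
        np.testing.assert_allclose(res.voxel_p_map.ravel(), p_ref, atol=1e-10)
        assert res.df == (4,)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.standard_normal((6, 2, 2, 2))
        b = rng.standard_normal((8, 2, 2, 2)) + 0.5
        res = one_way_anova([a, b], MASK8)
        t_ref, _ = stats.ttest_ind(a.reshape(6, -1), b.reshape(8, -1), axis=0)
        np.testing.assert_allclose(res.stat_map.ravel(), t_ref**2, atol=1e-9)
        assert res.df == (1, 12)

    def test_null_calibration_scalar_simulation(self, rng):
        voxels = 2000
        groups = [rng.standard_normal((8, voxels)) for _ in range(3)]
        res = one_way_anova(groups, np.ones(voxels, bool))
        frac = (res.voxel_p_map < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / voxels) + 0.01)

    def test_planted_shift_detected_only_at_planted_voxels(self, rng):
        a = rng.standard_normal((8, 4, 4, 4))
        b = rng.standard_normal((8, 4, 4, 4))
        c = rng.standard_normal((8, 4, 4, 4))
        c[:, 0, 0, 0] += 10.0
        res = one_way_anova([a, b, c], np.ones((4, 4, 4), bool))
        assert res.stat_map[0, 0, 0] > 50
        assert np.median(res.stat_map) < 5

    def test_covariate_df_charged(self, rng):
        groups = [rng.standard_normal((5, 2, 2, 2)) for _ in range(3)]
        cov = rng.standard_normal((15, 3))
        res = one_way_anova(groups, MASK8, covariates=cov)
        assert res.df == (2, 15 - 3 - 3)

    def test_group_smaller_than_two_rejected(self, rng):
        with pytest.raises(FcdPipeError, match=">= 2 subjects"):
            one_way_anova([rng.standard_normal((1, 8)),
                           rng.standard_normal((4, 8))], np.ones(8, bool))

    def test_subject_order_permutation_invariant(self, rng):
        a = rng.standard_normal((6, 2, 2, 2))
        b = rng.standard_normal((6, 2, 2, 2))
        res1 = one_way_anova([a, b], MASK8)
        perm = rng.permutation(6)
        res2 = one_way_anova([a[perm], b[perm[::-1]]], MASK8)
        np.testing.assert_allclose(res1.stat_map, res2.stat_map, atol=1e-10)


class TestPosthocT:
    def test_identical_groups_give_zero_t(self, rng):
        a = rng.standard_normal((6, 2, 2, 2))
        res = posthoc_t(a, a.copy(), MASK8)
        np.testing.assert_allclose(res.stat_map, 0.0, atol=1e-12)

    def test_swapping_groups_negates_t(self, rng):
        a = rng.standard_normal((6, 2, 2, 2))
        b = rng.standard_normal((7, 2, 2, 2))
        r1 = posthoc_t(a, b, MASK8)
        r2 = posthoc_t(b, a, MASK8)
        np.testing.assert_allclose(r1.stat_map, -r2.stat_map, atol=1e-12)

    def test_matches_scipy_two_sample_oracle(self, rng):
        a = rng.standard_normal((6, 2, 2, 2))
        b = rng.standard_normal((9, 2, 2, 2))
        res = posthoc_t(a, b, MASK8)
        t_ref, p_ref = stats.ttest_ind(a.reshape(6, -1), b.reshape(9, -1), axis=0)
        np.testing.assert_allclose(res.stat_map.ravel(), t_ref, atol=1e-10)
        np.testing.assert_allclose(res.voxel_p_map.ravel(), p_ref, atol=1e-10)

    def test_restriction_mask_respected(self, rng):
        a = rng.standard_normal((6, 2, 2, 2)) + 5
        b = rng.standard_normal((6, 2, 2, 2))
        restrict = np.zeros((2, 2, 2), bool)
        restrict[0, 0, 0] = True
        res = posthoc_t(a, b, restrict)
        assert res.stat_map[0, 0, 0] != 0
        assert np.all(res.stat_map[~restrict] == 0)
        assert np.all(res.voxel_p_map[~restrict] == 1.0)

    def test_empty_restriction_warns(self, rng):
        a = rng.standard_normal((4, 2, 2, 2))
        with pytest.warns(UserWarning, match="empty"):
            posthoc_t(a, a, np.zeros((2, 2, 2), bool))


class TestMonteCarloExtent:
    def test_alpha_one_gives_threshold_one(self):
        null = monte_carlo_extent_threshold(
            np.ones((6, 6, 6), bool), voxel_p=0.05, smoothness_fwhm_mm=6.0,
            alpha=1.0, n_iterations=100, seed=1,
        )
        assert null.extent_threshold == 1

    def test_single_voxel_mask_bernoulli(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        null = monte_carlo_extent_threshold(
            mask, voxel_p=0.05, smoothness_fwhm_mm=0.0, alpha=0.05,
            n_iterations=2000, seed=7,
        )
        p_hit = (null.max_cluster_sizes >= 1).mean()
        assert p_hit == pytest.approx(0.05, abs=0.02)
        assert null.extent_threshold == 1

    def test_deterministic_given_seed(self):
        kw = dict(voxel_p=0.05, smoothness_fwhm_mm=6.0, alpha=0.05,
                  n_iterations=150, seed=11)
        a = monte_carlo_extent_threshold(np.ones((8, 8, 8), bool), **kw)
        b = monte_carlo_extent_threshold(np.ones((8, 8, 8), bool), **kw)
        np.testing.assert_array_equal(a.max_cluster_sizes, b.max_cluster_sizes)
        assert a.extent_threshold == b.extent_threshold

    def test_threshold_monotone_in_voxel_p_and_smoothness(self):
        mask = np.ones((10, 10, 10), bool)
        base = dict(alpha=0.05, n_iterations=300, seed=3)
        k_strict = monte_carlo_extent_threshold(mask, voxel_p=0.01,
                                                smoothness_fwhm_mm=8.0, **base)
        k_loose = monte_carlo_extent_threshold(mask, voxel_p=0.05,
                                               smoothness_fwhm_mm=8.0, **base)
        k_rough = monte_carlo_extent_threshold(mask, voxel_p=0.05,
                                               smoothness_fwhm_mm=4.0, **base)
        assert k_strict.extent_threshold <= k_loose.extent_threshold
        assert k_rough.extent_threshold <= k_loose.extent_threshold

    def test_statistic_field_mode_runs_and_is_smaller(self):
        # a low-df F field is rougher than the smoothed Gaussian field, so
        # its null clusters are smaller
        mask = np.ones((10, 10, 10), bool)
        base = dict(voxel_p=0.05, smoothness_fwhm_mm=8.0, alpha=0.05,
                    n_iterations=200, seed=5)
        k_z = monte_carlo_extent_threshold(mask, **base)
        k_f = monte_carlo_extent_threshold(mask, group_sizes=(8, 8, 8),
                                           n_covariates=3, **base)
        assert k_f.extent_threshold <= k_z.extent_threshold

    def test_empty_mask_rejected(self):
        with pytest.raises(FcdPipeError, match="empty"):
            monte_carlo_extent_threshold(np.zeros((3, 3, 3), bool))


def stat_from_pmask(sig_mask, stat_values=None):
    """Build a StatResult whose suprathreshold voxels are sig_mask."""
    sig_mask = np.asarray(sig_mask, bool)
    stat = np.where(sig_mask, 5.0, 0.0) if stat_values is None else stat_values
    p = np.where(sig_mask, 0.01, 0.9)
    return StatResult(stat_map=stat, stat_kind="F", df=(2, 20), voxel_p_map=p,
                      mask=np.ones(sig_mask.shape, bool))


class TestExtractClusters:
    def test_no_suprathreshold_voxels_empty_table(self):
        ct = extract_clusters(stat_from_pmask(np.zeros((4, 4, 4), bool)))
        assert len(ct) == 0
        assert not ct.significant_mask().any()

    def test_extent_threshold_filters_small_blob(self):
        sig = np.zeros((8, 8, 8), bool)
        sig[1, 1, 1:5] = True        # 4-voxel blob
        sig[6, 6, 1:3] = True        # 2-voxel blob
        ct = extract_clusters(stat_from_pmask(sig), extent_threshold=3,
                              voxel_size_mm=3.0)
        assert len(ct) == 1
        row = ct.table.iloc[0]
        assert row.extent_voxels == 4
        assert row.extent_mm3 == pytest.approx(108.0)

    def test_connectivity_semantics_at_corner_touch(self):
        sig = np.zeros((6, 6, 6), bool)
        sig[1:3, 1:3, 1] = True
        sig[3:5, 3:5, 1] = True  # touches the first blob only at a corner
        assert len(extract_clusters(stat_from_pmask(sig), connectivity=26)) == 1
        assert len(extract_clusters(stat_from_pmask(sig), connectivity=6)) == 2

    def test_peak_and_coordinates(self):
        sig = np.zeros((5, 5, 5), bool)
        sig[2, 2, 2] = sig[2, 2, 3] = True
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2], stat[2, 2, 3] = 4.0, 7.5
        ct = extract_clusters(stat_from_pmask(sig, stat))
        row = ct.table.iloc[0]
        assert row.peak_stat == 7.5
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (6.0, 6.0, 9.0)

    def test_signed_directions(self):
        sig = np.zeros((5, 5, 5), bool)
        sig[1, 1, 1] = sig[3, 3, 3] = True
        stat = np.zeros((5, 5, 5))
        stat[1, 1, 1], stat[3, 3, 3] = 4.0, -4.0
        res = stat_from_pmask(sig, stat)
        assert len(extract_clusters(res, direction="pos")) == 1
        assert len(extract_clusters(res, direction="neg")) == 1
        assert len(extract_clusters(res, direction="two-sided")) == 2

    def test_peak_tie_broken_by_lowest_linear_index(self):
        sig = np.zeros((5, 5, 5), bool)
        sig[2, 2, 2] = sig[2, 2, 3] = True
        stat = np.where(sig, 3.0, 0.0)
        ct = extract_clusters(stat_from_pmask(sig, stat))
        assert (ct.table.iloc[0].peak_z_mm, ct.table.iloc[0].peak_y_mm) == (6.0, 6.0)
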