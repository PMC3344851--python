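"""Residualized beta maps, random-effects statistics, FDR and cluster-extent
thresholding."""

import numpy as np
import pytest
from scipy import ndimage, stats

import rsnselect as rs
from rsnselect.core import BoldRun
from rsnselect.group import (BetaMap, apply_cluster_threshold,
                             cluster_size_threshold, component_beta_map,
                             estimate_smoothness_fwhm, fdr_mask,
                             rfx_one_sample, residualize,
                             two_sample_contrast)

GRID = (5, 5, 4)


def run_from(data):
    return BoldRun(data=data, tr_seconds=2.0,
                   mask=np.ones(data.shape[:3], bool), voxel_mm=(3, 3, 3))


def beta_of(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return BetaMap(values=values, mask=mask)


class TestResidualize:
    def test_spanned_data_residual_zero(self):
        rng = np.random.default_rng(0)
        courses = rng.standard_normal((80, 4))
        weights = rng.standard_normal((np.prod(GRID), 3))
        data = (np.delete(courses, 2, axis=1) @ weights.T).T.reshape(
            GRID + (80,))
        out = residualize(run_from(data), courses, selected=2)
        assert np.abs(out.data).max() < 1e-8

    def test_orthogonal_selected_course_untouched(self):
        A = np.random.default_rng(1).standard_normal((80, 4))
        A -= A.mean(axis=0)                # orthogonal to the intercept too
        courses, _ = np.linalg.qr(A)
        data = np.tile(courses[:, 2], GRID + (1,))
        out = residualize(run_from(data), courses, selected=2)
        np.testing.assert_allclose(out.data, data, atol=1e-10)

    def test_two_step_equals_partial_regression(self):
        # Frisch-Waugh oracle: beta from residualize + simple regression
        # equals the full-model coefficient
        rng = np.random.default_rng(2)
        t, k = 100, 5
        courses = rng.standard_normal((t, k))
        data = rng.standard_normal(GRID + (t,))
        sel = 1
        resid = residualize(run_from(data), courses, selected=sel)
        from rsnselect.group import residualize_course
        bm = component_beta_map(resid,
                                residualize_course(courses[:, sel],
                                                   courses, sel))
        X = np.column_stack([np.ones(t), courses])
        full = np.linalg.lstsq(X, data.reshape(-1, t).T, rcond=None)[0]
        np.testing.assert_allclose(bm.values.ravel(), full[1 + sel],
                                   atol=1e-8)

    def test_selected_out_of_range(self):
        courses = np.random.default_rng(3).standard_normal((80, 4))
        with pytest.raises(ValueError):
            residualize(run_from(np.zeros(GRID + (80,))), courses, 4)


class TestComponentBetaMap:
    def test_known_slope(self):
        rng = np.random.default_rng(4)
        course = rng.standard_normal(80)
        data = np.tile(2.0 * course, GRID + (1,))
        bm = component_beta_map(run_from(data), course)
        np.testing.assert_allclose(bm.values, 2.0, atol=1e-10)

    def test_noise_betas_center_on_zero(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((10, 10, 10, 80))
        course = rng.standard_normal(80)
        bm = component_beta_map(run_from(data), course)
        assert abs(bm.values.mean()) < 3.0 / np.sqrt(1000 * 80)

    def test_network_blobs_light_up(self, bank):
        # ground-truth contrast oracle at snr 2: mean beta inside network
        # blobs dwarfs the background
        run, truth = rs.simulate_subject(bank, "control", n_volumes=120,
                                         seed=31, snr=2.0)
        pre = rs.preprocess(run)
        courses = truth.mixing
        sel = list(bank.labels).index("network")
        resid = residualize(pre, courses, selected=sel)
        bm = component_beta_map(resid, courses[:, sel])
        inside = bm.values[bank.network_mask].mean()
        outside_mask = ~ndimage.binary_dilation(
            bank.network_mask | bank.anti_mask, iterations=3)
        outside = np.abs(bm.values[outside_mask]).mean()
        assert inside >= 5 * outside

    def test_constant_course_rejected(self):
        with pytest.raises(ValueError):
            component_beta_map(run_from(np.zeros(GRID + (80,))),
                               np.ones(80))


class TestRfxOneSample:
    def test_matches_hand_computed_column(self):
        vals = [1.2, 0.8, 1.5, 1.1, 0.9]          # mean 1.1, sd 0.273861...
        maps = [beta_of(np.full(GRID, v)) for v in vals]
        stat = rfx_one_sample(maps)
        # textbook: t = 1.1 / (0.2738613.../sqrt(5)) = 8.981462...
        assert stat.dof == 4
        assert stat.tvalues[0, 0, 0] == pytest.approx(8.981462390204987)

    def test_consistent_positive_effect_large_t(self):
        rng = np.random.default_rng(6)
        maps = [beta_of(0.5 + 1e-4 * rng.standard_normal(GRID))
                for _ in range(8)]
        stat = rfx_one_sample(maps)
        assert stat.tvalues.min() > 100

    def test_dof_is_n_minus_one(self):
        maps = [beta_of(np.random.default_rng(i).standard_normal(GRID))
                for i in range(15)]
        assert rfx_one_sample(maps).dof == 14

    def test_zero_variance_flagged(self):
        maps = [beta_of(np.zeros(GRID)) for _ in range(4)]
        stat = rfx_one_sample(maps)
        assert (stat.tvalues == 0).all()
        assert stat.zero_variance.all()

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            rfx_one_sample([beta_of(np.zeros(GRID))] * 2)


class TestFdrMask:
    def stat_from_p(self, pvals, dof=20):
        # invert two-sided p to t, positive sign
        t = stats.t.isf(np.asarray(pvals) / 2, dof)
        grid = (len(pvals), 1, 1)
        return rs.StatMap(tvalues=t.reshape(grid), dof=dof,
                          kind="one_sample", mask=np.ones(grid, bool))

    def test_all_p_one_empty(self):
        stat = self.stat_from_p([1.0] * 50)
        assert not fdr_mask(stat, 0.05).any()

    def test_single_tiny_p_survives(self):
        p = [1e-12] + [0.8] * 9999
        stat = self.stat_from_p(p)
        mask = fdr_mask(stat, 0.05)
        assert mask.ravel()[0] and mask.sum() == 1

    def test_matches_step_up_enumeration(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(0, 0.2, 20))
        stat = self.stat_from_p(p)
        mask = fdr_mask(stat, 0.05).ravel()
        # brute-force Benjamini-Hochberg: largest k with p_(k) <= k q / m
        m, q = 20, 0.05
        ks = [k for k in range(1, m + 1) if p[k - 1] <= k * q / m]
        expected = np.zeros(m, bool)
        if ks:
            expected[:max(ks)] = True
        np.testing.assert_array_equal(mask, expected)

    def test_fdr_subset_of_uncorrected(self):
        rng = np.random.default_rng(8)
        t = rng.standard_normal((10, 10, 10)) * 2
        stat = rs.StatMap(tvalues=t, dof=25, kind="one_sample",
                          mask=np.ones(t.shape, bool))
        fdr = fdr_mask(stat, 0.05)
        p = 2 * stats.t.sf(np.abs(t), 25)
        assert not (fdr & ~(p < 0.05)).any()


class TestTwoSampleContrast:
    def test_dof_15_vs_13(self):
        g1 = [beta_of(np.random.default_rng(i).standard_normal(GRID))
              for i in range(15)]
        g2 = [beta_of(np.random.default_rng(100 + i).standard_normal(GRID))
              for i in range(13)]
        assert two_sample_contrast(g1, g2).dof == 26

    def test_identical_groups_zero(self):
        maps = [beta_of(np.random.default_rng(i).standard_normal(GRID))
                for i in range(4)]
        stat = two_sample_contrast(maps, maps)
        np.testing.assert_allclose(stat.tvalues, 0.0, atol=1e-12)

    def test_hand_computed_3v3(self):
        g1 = [beta_of(np.full(GRID, v)) for v in (4.0, 5.0, 6.0)]
        g2 = [beta_of(np.full(GRID, v)) for v in (1.0, 2.0, 3.0)]
        stat = two_sample_contrast(g1, g2)
        # pooled s2 = 1, t = 3 / sqrt(1 * (1/3 + 1/3)) = 3.674234...
        assert stat.dof == 4
        assert stat.tvalues[0, 0, 0] == pytest.approx(3.6742346141747673)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(9)
        g1 = [beta_of(rng.standard_normal(GRID)) for _ in range(4)]
        g2 = [beta_of(rng.standard_normal(GRID)) for _ in range(3)]
        s12 = two_sample_contrast(g1, g2)
        s21 = two_sample_contrast(g2, g1)
        np.testing.assert_allclose(s12.tvalues, -s21.tvalues, atol=1e-12)


class TestClusterThreshold:
    def test_independent_voxels_high_threshold_k1(self):
        k = cluster_size_threshold((16, 16, 16), voxel_t_threshold=6.0,
                                   dof=26, smoothness_mm=0.0,
                                   n_iterations=200, seed=0)
        assert k == 1

    def test_k_nonincreasing_in_voxel_threshold(self):
        ks = [cluster_size_threshold((16, 16, 16), t, dof=26,
                                     smoothness_mm=6.0, n_iterations=300,
                                     seed=1)
              for t in (2.0, 2.8, 3.5)]
        assert ks[0] >= ks[1] >= ks[2]

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            cluster_size_threshold((8, 8, 8), 2.0, 10, alpha=1.5,
                                   n_iterations=200)

    def test_smoothness_estimator_recovers_fwhm(self):
        rng = np.random.default_rng(10)
        maps = [ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)),
                                        8.0 / 2.3548 / 3.0)
                for _ in range(6)]
        est = estimate_smoothness_fwhm(maps, (3.0, 3.0, 3.0))
        assert est == pytest.approx(8.0, rel=0.15)


class TestApplyClusterThreshold:
    def stat_of(self, t):
        return rs.StatMap(tvalues=t, dof=26, kind="two_sample",
                          mask=np.ones(t.shape, bool))

    def test_empty_when_nothing_suprathreshold(self):
        table = apply_cluster_threshold(self.stat_of(np.zeros((8, 8, 8))),
                                        2.0, 1)
        assert len(table) == 0

    def test_min_size_boundary(self):
        t = np.zeros((10, 10, 10))
        t[2:4, 3:8, 5] = 5.0                      # 10-voxel slab
        assert len(apply_cluster_threshold(self.stat_of(t), 2.0, 11)) == 0
        table = apply_cluster_threshold(self.stat_of(t), 2.0, 10)
        assert len(table) == 1
        assert table.size_voxels.iloc[0] == 10
        assert table.sign.iloc[0] == "positive"

    def test_signs_labelled_separately(self):
        t = np.zeros((10, 10, 10))
        t[1, 1, 1] = 5.0
        t[1, 1, 2] = -5.0                         # adjacent opposite signs
        table = apply_cluster_threshold(self.stat_of(t), 2.0, 1)
        assert sorted(table.sign) == ["negative", "positive"]

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        t = np.where(rng.random((12, 12, 12)) < 0.2, 5.0, 0.0)
        table = apply_cluster_threshold(self.stat_of(t), 2.0, 1)

        # 26-connectivity flood fill
        supra = t > 2.0
        seen = np.zeros_like(supra)
        sizes = []
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            stack, size = [start], 0
            seen[start] = True
            while stack:
                v = stack.pop()
                size += 1
                for o in offs:
                    w = tuple(np.add(v, o))
                    if all(0 <= w[d] < 12 for d in range(3)) \
                            and supra[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            sizes.append(size)
        assert sorted(table.size_voxels) == sorted(sizes)
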