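import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter1d

import landing_xlr as lx
from landing_xlr.channels import CHANNELS
from landing_xlr.relevance import HighRsSet
from landing_xlr.spm import (
    ConcordanceReport,
    concordance,
    effect_size_r,
    estimate_fwhm,
    paired_t_trajectory,
    permutation_threshold,
    rft_threshold,
    spm_paired_t,
)


def smooth_null_field(rng, n, q, sigma):
    pad = int(6 * sigma)
    white = rng.normal(size=(n, q + 2 * pad))
    return gaussian_filter1d(white, sigma, axis=1)[:, pad : pad + q]


class TestPairedT:
    def test_identical_matrices_zero_t(self):
        a = np.random.default_rng(0).normal(size=(5, 11))
        t, df = paired_t_trajectory(a, a.copy())
        assert df == 4
        assert np.isnan(t).all() or np.allclose(np.nan_to_num(t), 0.0)

    def test_hand_computed_single_node(self):
        # d = {1, 2, 3}: t = 2 / (1 / sqrt(3)) = 2 sqrt(3)
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.zeros((3, 1))
        t, df = paired_t_trajectory(a, b)
        assert df == 2
        assert t[0] == pytest.approx(2.0 * np.sqrt(3.0))
        assert t[0] == pytest.approx(3.464, abs=1e-3)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=(6, 13))
        b = rng.normal(size=(6, 13))
        t_ab, _ = paired_t_trajectory(a, b)
        t_ba, _ = paired_t_trajectory(b, a)
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=(8, 21))
            b = rng.normal(size=(8, 21))
            t, df = paired_t_trajectory(a, b)
            expected = stats.ttest_rel(a, b, axis=0)
            np.testing.assert_allclose(t, expected.statistic, atol=1e-10)
            assert df == expected.df[0]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            paired_t_trajectory(np.ones((1, 5)), np.zeros((1, 5)))

    def test_zero_variance_node_flagged(self):
        a = np.ones((4, 3))
        a[:, 0] = [1, 2, 3, 4]
        b = np.zeros((4, 3))
        res = spm_paired_t(a, b)
        assert 1 in res.zero_variance_nodes and 2 in res.zero_variance_nodes


class TestFwhm:
    def test_upsampled_smoother(self, rng):
        r = rng.normal(size=(6, 40))
        fine = np.apply_along_axis(
            lambda row: np.interp(np.linspace(0, 39, 79), np.arange(40), row), 1, r
        )
        assert estimate_fwhm(fine) > estimate_fwhm(r)

    def test_convolved_noise_larger_fwhm(self):
        wins = 0
        for seed in range(7):
            rng = np.random.default_rng(seed)
            white = rng.normal(size=(8, 101))
            smooth = gaussian_filter1d(white, 4.0, axis=1)
            if estimate_fwhm(smooth) > estimate_fwhm(white):
                wins += 1
        assert wins >= 5  # repeated-seed majority

    def test_constant_residuals_capped(self):
        assert estimate_fwhm(np.ones((4, 10))) >= 1e5

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            estimate_fwhm(np.ones((4, 1)))


class TestRftThreshold:
    def test_one_resel_limit_is_pointwise_quantile(self):
        t_crit = rft_threshold(df=9, fwhm=1e9, n_nodes=101, alpha=0.05)
        assert t_crit == pytest.approx(stats.t.isf(0.025, 9), rel=1e-6)

    def test_monotone_nonincreasing_in_fwhm(self):
        prev = np.inf
        for fwhm in (2.0, 5.0, 10.0, 25.0, 100.0):
            t_crit = rft_threshold(df=9, fwhm=fwhm, n_nodes=101, alpha=0.05)
            assert t_crit <= prev + 1e-12
            prev = t_crit

    def test_ordering_law(self):
        for df in (3, 9, 20, 55):
            for fwhm in (1.0, 3.0, 10.0, 30.0, 300.0):
                t_crit = rft_threshold(df, fwhm, 101, 0.05)
                lo = stats.t.isf(0.025, df)
                hi = stats.t.isf(0.05 / (2 * 101), df)
                assert lo - 1e-12 <= t_crit <= hi + 1e-12

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            rft_threshold(9, 10.0, 101, 0.0)

    def test_null_calibration(self):
        # family-wise error on smooth Gaussian null fields ~ alpha
        rng = np.random.default_rng(555)
        n, q, sigma, n_sim = 10, 101, 5.0, 1000
        hits = 0
        for _ in range(n_sim):
            field = smooth_null_field(rng, n, q, sigma)
            t = field.mean(0) / (field.std(0, ddof=1) / np.sqrt(n))
            resid = field - field.mean(0)
            t_crit = rft_threshold(n - 1, estimate_fwhm(resid), q, 0.05)
            hits += np.abs(t).max() > t_crit
        rate = hits / n_sim
        band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= band


class TestPermutation:
    def test_alpha_one_gives_distribution_minimum(self, rng):
        d = rng.normal(size=(8, 21))
        thr = permutation_threshold(d, alpha=1.0 - 1e-12, n_perm=200, seed=1)
        assert thr > 0

    def test_deterministic(self, rng):
        d = rng.normal(size=(8, 21))
        a = permutation_threshold(d, n_perm=300, seed=7)
        b = permutation_threshold(d, n_perm=300, seed=7)
        assert a == b

    def test_agrees_with_rft_on_smooth_nulls(self):
        rels = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = smooth_null_field(rng, 12, 101, 5.0)
            perm = permutation_threshold(d, alpha=0.05, n_perm=800, seed=seed)
            resid = d - d.mean(0)
            rft = rft_threshold(11, estimate_fwhm(resid), 101, 0.05)
            rels.append(abs(perm - rft) / rft)
        assert np.median(rels) <= 0.10

    def test_few_subjects_warning(self):
        d = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.warns(UserWarning, match="sign patterns"):
            permutation_threshold(d, alpha=0.01, n_perm=100, seed=0)


class TestEffectSize:
    def test_zero_t(self):
        assert effect_size_r(0.0, 9).r[0] == 0.0

    def test_large_t_limit(self):
        assert effect_size_r(1e9, 9).r[0] == pytest.approx(1.0)

    def test_closed_form(self):
        # r = sqrt(t^2 / (t^2 + df)) at t=3, df=9 -> sqrt(9/18)
        assert effect_size_r(3.0, 9).r[0] == pytest.approx(np.sqrt(0.5))
        assert effect_size_r(3.0, 9).r[0] == pytest.approx(0.7071, abs=1e-4)

    def test_bands_partition(self):
        traj = effect_size_r(np.array([0.1, 3.0, 100.0]), 9)
        assert traj.bands.tolist() == [0, 1, 2]

    def test_monotone_in_abs_t(self):
        t = np.linspace(-5, 5, 41)
        r = effect_size_r(t, 9).r
        assert (np.diff(r[t >= 0]) >= 0).all()
        np.testing.assert_allclose(r, r[::-1], atol=1e-12)  # depends on |t|


class TestConcordance:
    def _high_rs(self, channel, start, end):
        return HighRsSet(threshold=0.7, runs=[(channel, start, end)])

    def _spm(self, clusters, q=101):
        from landing_xlr.spm import SpmResult

        return SpmResult(
            t=np.zeros(q), df=9, fwhm=10.0, t_crit=3.0, clusters=clusters, alpha=0.05
        )

    def test_identical_sets(self):
        ch = CHANNELS[0]
        rep = concordance(self._high_rs(ch, 10, 20), {ch: self._spm([(10, 20)])})
        assert rep.per_channel[ch.label]["jaccard"] == 1.0

    def test_disjoint_sets(self):
        ch = CHANNELS[0]
        rep = concordance(self._high_rs(ch, 0, 5), {ch: self._spm([(50, 60)])})
        assert rep.per_channel[ch.label]["jaccard"] == 0.0

    def test_partial_overlap_inclusive_counting(self):
        # RS nodes 10..20 (11), cluster 15..25 (11): intersection 15..20 = 6,
        # union 10..25 = 16 -> Jaccard 6/16 = 0.375
        ch = CHANNELS[0]
        rep = concordance(self._high_rs(ch, 10, 20), {ch: self._spm([(15, 25)])})
        stats_ = rep.per_channel[ch.label]
        assert stats_["n_intersection"] == 6
        assert stats_["jaccard"] == pytest.approx(6 / 16)
        assert stats_["coverage_of_rs"] == pytest.approx(6 / 11)
        assert stats_["coverage_of_spm"] == pytest.approx(6 / 11)

    def test_grid_mismatch(self):
        ch = CHANNELS[0]
        with pytest.raises(ValueError, match="grid"):
            concordance(
                self._high_rs(ch, 0, 5),
                {ch: self._spm([(0, 5)], q=101), CHANNELS[1]: self._spm([], q=51)},
            )


class TestEndToEndSpm:
    def test_clusters_cover_injected_window(self):
        from landing_xlr.pipeline import benchmark_generator
        from landing_xlr.synth import CLASS_AFTER, CLASS_BEFORE, generate_dataset
        from landing_xlr.channels import CHANNEL_INDEX

        ds = generate_dataset(benchmark_generator(n_subjects=12, n_trials=3, seed=5))
        before = ds.subject_means(CLASS_BEFORE)
        after = ds.subject_means(CLASS_AFTER)
        ci = CHANNEL_INDEX[lx.ChannelId(lx.Joint.KNEE, lx.Plane.SAGITTAL, lx.Quantity.ANGLE)]
        res = spm_paired_t(after[:, ci, :], before[:, ci, :], alpha=0.05)
        covered = res.supra_nodes()
        window = set(range(15, 25))
        coverage = len(covered & window) / len(window)
        assert coverage >= 0.8
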