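import numpy as np
import pytest

import landing_xlr as lx
from landing_xlr.channels import CHANNELS
from landing_xlr.lrp import RelevanceMap
from landing_xlr.relevance import (
    HighRsSet,
    MapStateError,
    SmoothingSpec,
    aggregate_contributions,
    average_maps,
    extract_high_rs,
    scale_rs,
    smooth_rs,
)
from conftest import random_relevance_map

# (0.25, 0.5, 0.25) convolved with itself twice, computed by polynomial
# multiplication: (1,2,1)^3 / 4^3 = (1,6,15,20,15,6,1) / 64
KERNEL_CUBED = np.array([1, 6, 15, 20, 15, 6, 1]) / 64.0


def grid_map(values, state="raw"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return RelevanceMap(values=values, channels=CHANNELS[: len(values)], state=state)


class TestAverage:
    def test_mean_of_zero_and_one(self):
        m0 = grid_map(np.zeros((1, 5)))
        m1 = grid_map(np.ones((1, 5)))
        avg = average_maps([m0, m1], selection="all")
        np.testing.assert_array_equal(avg.values, 0.5 * np.ones((1, 5)))

    def test_single_map_identity(self):
        m = grid_map([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(average_maps([m], selection="all").values, m.values)

    def test_correct_only_selection(self, small_run):
        maps = small_run["maps"]
        n_correct = sum(m.meta["correct"] for m in maps)
        avg = average_maps(maps, selection="correct")
        assert avg.meta["n_averaged"] == n_correct

    def test_rectification_clips_negatives(self):
        m = grid_map([[-1.0, 1.0]])
        avg = average_maps([m], selection="all")
        np.testing.assert_array_equal(avg.values, [[0.0, 1.0]])
        signed = average_maps([m], selection="all", rectify=False)
        np.testing.assert_array_equal(signed.values, [[-1.0, 1.0]])

    def test_empty_selection_error(self):
        with pytest.raises(ValueError):
            average_maps([], selection="all")


class TestSmoothing:
    def test_constant_series_unchanged(self):
        m = grid_map(np.full((1, 11), 3.5))
        out = smooth_rs(m, SmoothingSpec(repetitions=1))
        np.testing.assert_allclose(out.values, 3.5)

    def test_impulse_response_single_pass(self):
        row = np.zeros(11)
        row[5] = 1.0
        out = smooth_rs(grid_map([row]), SmoothingSpec(repetitions=1))
        expected = np.zeros(11)
        expected[4:7] = [0.25, 0.5, 0.25]
        np.testing.assert_allclose(out.values[0], expected)

    def test_three_passes_equal_kernel_cubed(self):
        row = np.zeros(21)
        row[10] = 1.0
        out = smooth_rs(grid_map([row]), SmoothingSpec(repetitions=3))
        expected = np.zeros(21)
        expected[7:14] = KERNEL_CUBED
        np.testing.assert_allclose(out.values[0], expected, atol=1e-15)

    def test_replicate_boundary_preserves_sum(self):
        rng = np.random.default_rng(1)
        row = rng.uniform(size=31)
        out = smooth_rs(grid_map([row]), SmoothingSpec(repetitions=3, boundary="replicate"))
        assert out.values.sum() == pytest.approx(row.sum(), rel=1e-12)

    def test_renormalize_boundary_preserves_constants(self):
        m = grid_map(np.full((1, 7), 2.0))
        out = smooth_rs(m, SmoothingSpec(repetitions=3, boundary="renormalize"))
        np.testing.assert_allclose(out.values, 2.0)

    def test_smoothing_scaled_map_rejected(self):
        m = grid_map([[0.0, 0.5, 1.0]], state="scaled")
        with pytest.raises(MapStateError):
            smooth_rs(m)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SmoothingSpec(weights=(0.3, 0.5, 0.3))
        with pytest.raises(ValueError):
            SmoothingSpec(repetitions=-1)


class TestScaling:
    def test_three_values(self):
        m = grid_map([[2.0, 4.0, 6.0]], state="smoothed")
        out = scale_rs(m)
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])
        assert out.state == "scaled"

    def test_already_unit_interval_unchanged(self):
        m = grid_map([[0.0, 0.25, 1.0]], state="smoothed")
        np.testing.assert_allclose(scale_rs(m).values, m.values)

    def test_constant_map_warns_and_zeroes(self):
        m = grid_map([[1.0, 1.0, 1.0]], state="smoothed")
        with pytest.warns(UserWarning, match="degenerate"):
            out = scale_rs(m)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_per_channel_scope(self):
        m = grid_map([[0.0, 1.0], [0.0, 10.0]], state="smoothed")
        out = scale_rs(m, per_channel=True)
        np.testing.assert_allclose(out.values, [[0.0, 1.0], [0.0, 1.0]])

    def test_requires_smoothed_state(self):
        with pytest.raises(MapStateError):
            scale_rs(grid_map([[1.0, 2.0]], state="raw"))


class TestAggregation:
    def test_uniform_map_shares(self):
        m = RelevanceMap(
            values=np.ones((18, 101)), channels=CHANNELS, state="scaled"
        )
        table = aggregate_contributions(m)
        for share in table.channel_share.values():
            assert share == pytest.approx(100.0 / 18)
        for share in table.joint_share.values():
            assert share == pytest.approx(100.0 / 3)
        for share in table.plane_share.values():
            assert share == pytest.approx(100.0 / 3)
        # 22 bins (1..22 inclusive) of 101
        assert table.early_share == pytest.approx(22 / 101 * 100)

    def test_knee_only_map(self):
        values = np.zeros((18, 101))
        for i, ch in enumerate(CHANNELS):
            if ch.joint is lx.Joint.KNEE:
                values[i] = 1.0
        m = RelevanceMap(values=values, channels=CHANNELS, state="scaled")
        table = aggregate_contributions(m)
        assert table.joint_share["knee"] == pytest.approx(100.0)
        assert table.joint_share["ankle"] == pytest.approx(0.0)
        assert table.joint_share["hip"] == pytest.approx(0.0)

    def test_partitions_sum_to_100(self, rng):
        for _ in range(100):
            m = random_relevance_map(rng)
            table = aggregate_contributions(m)
            assert sum(table.channel_share.values()) == pytest.approx(100.0, abs=1e-6)
            assert sum(table.joint_share.values()) == pytest.approx(100.0, abs=1e-6)
            assert sum(table.plane_share.values()) == pytest.approx(100.0, abs=1e-6)
            assert table.phase_share.sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_total_error(self):
        m = RelevanceMap(values=np.zeros((18, 101)), channels=CHANNELS, state="scaled")
        with pytest.raises(ValueError, match="zero total"):
            aggregate_contributions(m)


class TestHighRs:
    def test_all_below_threshold(self):
        m = RelevanceMap(
            values=np.full((18, 101), 0.7), channels=CHANNELS, state="scaled"
        )
        hs = extract_high_rs(m)  # strictly greater than
        assert hs.runs == []
        assert hs.n_nodes_total == 0

    def test_single_run_reported(self):
        values = np.zeros((18, 101))
        values[6, 15:20] = 0.9
        m = RelevanceMap(values=values, channels=CHANNELS, state="scaled")
        hs = extract_high_rs(m, threshold=0.7)
        assert hs.runs == [(CHANNELS[6], 15, 19)]
        assert hs.n_nodes_total == 5

    def test_counts_match_brute_force_scan(self, rng):
        # oracle: full-grid node scan, independent of the run-length encoder
        for _ in range(20):
            m = random_relevance_map(rng)
            hs = extract_high_rs(m, threshold=0.7)
            brute = int((m.values > 0.7).sum())
            assert hs.n_nodes_total == brute
            for ch, start, end in hs.runs:
                row = m.values[list(m.channels).index(ch)]
                assert (row[start : end + 1] > 0.7).all()
                if start > 0:
                    assert row[start - 1] <= 0.7  # maximality
                if end < len(row) - 1:
                    assert row[end + 1] <= 0.7

    def test_unscaled_map_rejected(self):
        m = RelevanceMap(values=np.zeros((1, 5)), channels=CHANNELS[:1], state="raw")
        with pytest.raises(MapStateError):
            extract_high_rs(m)


class TestEffectWindowRecovery:
    def test_headline_property(self, small_run):
        """Injected channel dominates and its top-decile nodes hit the window."""
        maps = small_run["maps"]
        scaled = scale_rs(smooth_rs(average_maps(maps)))
        table = aggregate_contributions(scaled)
        assert max(table.joint_share, key=table.joint_share.get) == "knee"
        row = scaled.values[[c.label for c in scaled.channels].index("knee_sagittal_angle")]
        k = int(np.ceil(0.1 * len(row)))
        top = set(np.argsort(row)[-k:].tolist())
        window = set(range(15, 25))
        jaccard = len(top & window) / len(top | window)
        assert jaccard >= 0.5
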