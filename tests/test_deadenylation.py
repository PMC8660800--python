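"""Gel calibration, modal-tail extraction and apparent-rate estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from decaykit import (
    calibrate,
    estimate_rate,
    fold_inhibition,
    lanes_to_tail_series,
    most_abundant_tail,
    simulate_lane_profiles,
)
from decaykit.deadenylation import LaneProfile, RateEstimate, subtract_background


def _marker_table(positions, tails):
    return pd.DataFrame({"position": positions, "tail_nt": tails})


class TestCalibrate:
    def test_linear_midpoint(self):
        cal = calibrate(_marker_table([10, 50], [27, 7]))
        assert cal.position_to_tail(30) == pytest.approx(17.0)

    def test_identity_at_marker_positions(self):
        cal = calibrate(_marker_table([10, 30, 50, 70], [27, 22, 17, 12]))
        np.testing.assert_allclose(
            cal.position_to_tail([10, 30, 50, 70]), [27, 22, 17, 12]
        )

    def test_non_monotone_markers_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            calibrate(_marker_table([10, 30, 50], [27, 30, 7]))

    def test_extrapolation_clamped(self):
        cal = calibrate(_marker_table([10, 50], [27, 7]))
        assert cal.position_to_tail(0) == 27.0
        assert cal.position_to_tail(99) == 7.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_interpolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 8)
        pos = np.sort(rng.uniform(0, 100, n))
        pos += np.arange(n) * 1e-3  # strictly increasing
        tails = np.sort(rng.uniform(7, 200, n))[::-1]
        cal = calibrate(_marker_table(pos, tails))
        query = rng.uniform(pos.min(), pos.max(), 20)
        # independent oracle: manual piecewise-linear interpolation
        expected = [
            tails[i] + (tails[i + 1] - tails[i]) * (q - pos[i]) / (pos[i + 1] - pos[i])
            for q in query
            for i in [np.searchsorted(pos, q, side="right") - 1]
        ]
        np.testing.assert_allclose(cal.position_to_tail(query), expected, atol=1e-9)


class TestMostAbundantTail:
    def _cal(self):
        return calibrate(_marker_table([10, 30, 50, 70, 90], [27, 22, 17, 12, 7]))

    def test_single_band_at_a20(self):
        grid = np.arange(0, 100, 0.5)
        lane = LaneProfile(grid, np.exp(-0.5 * ((grid - 10) / 2) ** 2))
        assert most_abundant_tail(lane, self._cal()) == pytest.approx(20.0)

    def test_tie_broken_toward_longer_tail(self):
        grid = np.arange(0, 100, 1.0)
        intensity = np.zeros_like(grid)
        intensity[30] = 1.0  # 22 nt -> 15 As
        intensity[50] = 1.0  # 17 nt -> 10 As
        lane = LaneProfile(grid, intensity)
        assert most_abundant_tail(lane, self._cal(), background_window=3) == 15.0

    def test_all_zero_profile_errors(self):
        grid = np.arange(0, 100, 1.0)
        lane = LaneProfile(grid, np.zeros_like(grid))
        with pytest.raises(ValueError, match="zero"):
            most_abundant_tail(lane, self._cal())

    def test_background_offset_removed(self):
        grid = np.arange(0, 100, 0.5)
        band = np.exp(-0.5 * ((grid - 50) / 2) ** 2)
        lifted = LaneProfile(grid, band + 5.0)
        assert most_abundant_tail(lifted, self._cal()) == pytest.approx(10.0)
        sub = subtract_background(lifted)
        assert sub.min() == pytest.approx(0.0)

    def test_noisy_simulated_lanes_recover_truth(self):
        sim = simulate_lane_profiles(0.625, [0, 8, 16, 24], noise_sd=0.05, seed=13)
        cal = calibrate(sim.marker_table)
        for lane, truth in zip(sim.profiles, sim.truth["tail_As"]):
            got = most_abundant_tail(lane, cal, body_nt=sim.body_nt)
            assert got == pytest.approx(truth, abs=0.5)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_argmax_position_monotone_in_tail(self, seed):
        """With a monotone calibration, a band at a smaller position always
        reports a longer tail."""
        cal = self._cal()
        rng = np.random.default_rng(seed)
        grid = np.arange(0, 100, 0.5)
        c1, c2 = np.sort(rng.uniform(12, 88, 2))
        lane1 = LaneProfile(grid, np.exp(-0.5 * ((grid - c1) / 2) ** 2))
        lane2 = LaneProfile(grid, np.exp(-0.5 * ((grid - c2) / 2) ** 2))
        assert most_abundant_tail(lane1, cal) >= most_abundant_tail(lane2, cal)


class TestEstimateRate:
    def test_exact_ladder(self):
        series = pd.DataFrame({"time_min": [0, 8, 16, 24],
                               "tail_As": [20, 15, 10, 5]})
        est = estimate_rate(series)
        assert est.rate_As_per_min == pytest.approx(0.625, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_tails_rate_zero(self):
        series = pd.DataFrame({"time_min": [0, 8, 16], "tail_As": [20, 20, 20]})
        assert estimate_rate(series).rate_As_per_min == 0.0

    def test_plateau_points_excluded(self):
        """Fully deadenylated lanes would flatten the slope; they are cut."""
        series = pd.DataFrame(
            {"time_min": [0, 8, 16, 24, 32, 40],
             "tail_As": [20, 10, 0, 0, 0, 0]}
        )
        est = estimate_rate(series)
        assert est.n_points == 3
        assert est.rate_As_per_min == pytest.approx(1.25, abs=1e-12)
        no_excl = estimate_rate(series, exclude_plateau=False)
        assert no_excl.rate_As_per_min < est.rate_As_per_min

    def test_too_few_points_raise(self):
        series = pd.DataFrame({"time_min": [0, 8, 16], "tail_As": [20, 1, 0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            estimate_rate(series)

    def test_positive_slope_warned_and_floored(self):
        series = pd.DataFrame({"time_min": [0, 8, 16], "tail_As": [5, 10, 15]})
        with pytest.warns(UserWarning, match="positive"):
            est = estimate_rate(series)
        assert est.rate_As_per_min == 0.0


class TestFoldInhibition:
    def _est(self, rate, stderr=0.02):
        return RateEstimate(rate_As_per_min=rate, intercept_As=20.0,
                            r_squared=1.0, stderr=stderr, n_points=4)

    def test_fourfold(self):
        assert fold_inhibition(self._est(1.0), self._est(0.25)).fold == 4.0

    def test_equal_rates(self):
        assert fold_inhibition(self._est(0.8), self._est(0.8)).fold == 1.0

    def test_se_propagation_matches_delta_method(self):
        ref, test = self._est(1.2, 0.05), self._est(0.35, 0.03)
        res = fold_inhibition(ref, test)
        assert res.fold == pytest.approx(1.2 / 0.35)
        expected_se = res.fold * np.hypot(0.05 / 1.2, 0.03 / 0.35)
        assert res.stderr == pytest.approx(expected_se)

    def test_zero_test_rate_reported_as_bound(self):
        res = fold_inhibition(self._est(1.0), self._est(0.0, stderr=0.04))
        assert res.bound
        assert res.fold == pytest.approx(25.0)
        assert str(res).startswith(">")


class TestEndToEnd:
    @pytest.mark.parametrize("rate, times", [
        (0.25, [0, 8, 16, 24]),
        (0.625, [0, 8, 16, 24]),
        (1.25, [0, 4, 8, 12]),
    ])
    def test_rate_recovered_within_5_percent(self, rate, times):
        sim = simulate_lane_profiles(rate, times, seed=31)
        cal = calibrate(sim.marker_table)
        series = lanes_to_tail_series(sim.profiles, cal, body_nt=sim.body_nt)
        est = estimate_rate(series)
        assert est.rate_As_per_min == pytest.approx(rate, rel=0.05)

    def test_fold_reduction_recovered_within_10_percent(self):
        ctrl_sim = simulate_lane_profiles(1.225, [0, 4, 8, 12], seed=41)
        inhib_sim = simulate_lane_profiles(0.35, [0, 16, 32, 48], seed=42)
        results = []
        for sim in (ctrl_sim, inhib_sim):
            cal = calibrate(sim.marker_table)
            series = lanes_to_tail_series(sim.profiles, cal, body_nt=sim.body_nt)
            results.append(estimate_rate(series))
        res = fold_inhibition(*results)
        assert res.fold == pytest.approx(1.225 / 0.35, rel=0.10)
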