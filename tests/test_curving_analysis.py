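import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormloop import (
    Trajectory,
    WalkConfig,
    compute_curving,
    curving_histogram,
    mean_curving,
    mean_curving_fixed_distance,
    mean_curving_fixed_time,
    simulate_trajectory,
    total_signed_turning_deg,
)
from wormloop.errors import DegenerateTrackError, ParameterError, WormloopError
from wormloop._geometry import wrap_angle_deg

from conftest import make_circle_track, make_straight_track


def brute_force_curving(traj, min_step=0.0):
    """Independent oracle: wrapped heading differences over the raw polyline."""
    x, y = traj.x, traj.y
    headings = np.degrees(np.arctan2(np.diff(y), np.diff(x)))
    lengths = np.hypot(np.diff(x), np.diff(y))
    out_c, out_w = [], []
    for i in range(1, len(headings)):
        d = headings[i] - headings[i - 1]
        while d <= -180:
            d += 360
        while d > 180:
            d -= 360
        w = (lengths[i - 1] + lengths[i]) / 2
        out_c.append(d / w)
        out_w.append(w)
    return np.array(out_c), np.array(out_w)


class TestWrapAngle:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0.0, 0.0), (90.0, 90.0), (-90.0, -90.0), (190.0, -170.0), (-190.0, 170.0),
         (180.0, 180.0), (-180.0, 180.0), (540.0, 180.0)],
    )
    def test_wraps_into_half_open_interval_with_positive_reversals(self, raw, expected):
        assert wrap_angle_deg(raw) == pytest.approx(expected)


class TestComputeCurving:
    def test_collinear_points_give_zero(self):
        tr = make_straight_track(20.0)
        np.testing.assert_allclose(compute_curving(tr).curving_deg_per_mm, 0.0, atol=1e-12)

    def test_ccw_circle_constant_rate_matches_analytic_value(self):
        # radius 5 mm: 360 / (2*pi*5) = 11.459 deg/mm
        tr = make_circle_track(5.0, 0.5, 60.0, ccw=True, ventral_is_left=None)
        series = compute_curving(tr)
        assert series.sign_convention == "ccw_positive"
        # chord-based headings overestimate the arc rate by ~dtheta^2/24 (4e-4)
        np.testing.assert_allclose(series.curving_deg_per_mm, 11.4591559, rtol=1e-3)

    def test_cw_circle_negates(self):
        tr = make_circle_track(5.0, 0.5, 60.0, ccw=False, ventral_is_left=None)
        np.testing.assert_allclose(
            compute_curving(tr).curving_deg_per_mm, -11.4591559, rtol=1e-3
        )

    def test_matches_brute_force_oracle_on_noisy_walk(self):
        tr = simulate_trajectory(
            WalkConfig(bias_deg_per_mm=4.0, noise_deg_per_mm_sd=6.0, duration_s=200, seed=8)
        )
        expected_c, expected_w = brute_force_curving(tr)
        series = compute_curving(tr, min_step_mm=0.0)
        np.testing.assert_allclose(series.curving_deg_per_mm, expected_c, atol=1e-9)
        np.testing.assert_allclose(series.step_lengths_mm, expected_w, atol=1e-12)

    def test_ventral_right_flips_sign(self):
        left = make_circle_track(5.0, 0.5, 30.0, ventral_is_left=True)
        right = make_circle_track(5.0, 0.5, 30.0, ventral_is_left=False)
        np.testing.assert_allclose(
            compute_curving(left).curving_deg_per_mm,
            -compute_curving(right).curving_deg_per_mm,
        )

    def test_mirror_image_negates_series(self):
        tr = simulate_trajectory(
            WalkConfig(bias_deg_per_mm=3.0, noise_deg_per_mm_sd=5.0, duration_s=150, seed=4)
        )
        mirrored = Trajectory(tr.animal_id, tr.t, tr.x, -tr.y, ventral_is_left=None)
        base = Trajectory(tr.animal_id, tr.t, tr.x, tr.y, ventral_is_left=None)
        np.testing.assert_allclose(
            compute_curving(mirrored).curving_deg_per_mm,
            -compute_curving(base).curving_deg_per_mm,
            atol=1e-9,
        )

    @given(
        angle=st.floats(0, 2 * math.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, angle, dx, dy):
        tr = simulate_trajectory(
            WalkConfig(bias_deg_per_mm=-6.0, noise_deg_per_mm_sd=4.0, duration_s=80, seed=2)
        )
        c, s = math.cos(angle), math.sin(angle)
        moved = Trajectory(
            tr.animal_id,
            tr.t,
            c * tr.x - s * tr.y + dx,
            s * tr.x + c * tr.y + dy,
            ventral_is_left=tr.ventral_is_left,
        )
        np.testing.assert_allclose(
            compute_curving(moved).curving_deg_per_mm,
            compute_curving(tr).curving_deg_per_mm,
            atol=1e-8,
        )

    def test_short_steps_filtered_and_degenerate_track_raises(self):
        # jittery track whose motion never clears the minimum step
        t = np.arange(5, dtype=float)
        tr = Trajectory("jitter", t, 1e-4 * t, np.zeros(5))
        with pytest.raises(DegenerateTrackError):
            compute_curving(tr, min_step_mm=0.05)

    def test_step_weights_sum_close_to_path_length(self):
        tr = make_circle_track(5.0, 0.5, 60.0)
        series = compute_curving(tr)
        # centred weights omit half of the first and last step (equal chords here)
        chord = tr.path_length() / (len(tr) - 1)
        assert series.step_lengths_mm.sum() == pytest.approx(
            tr.path_length() - chord, abs=1e-9
        )


class TestClosedLoopTurning:
    def test_noise_free_loop_accumulates_360_per_circuit(self):
        cfg = WalkConfig(bias_deg_per_mm=11.4591559, speed_mm_per_s=0.5, duration_s=64)
        tr = simulate_trajectory(cfg)
        total = total_signed_turning_deg(compute_curving(tr))
        step_turn = 11.4591559 * 0.5
        assert abs(total - 360.0) <= step_turn + 1e-9

    def test_cw_loop_accumulates_minus_360(self):
        cfg = WalkConfig(bias_deg_per_mm=-11.4591559, speed_mm_per_s=0.5, duration_s=64)
        total = total_signed_turning_deg(compute_curving(simulate_trajectory(cfg)))
        assert abs(total + 360.0) <= 11.4591559 * 0.5 + 1e-9


class TestMeans:
    def test_fixed_time_zero_series(self):
        series = compute_curving(make_straight_track(100.0))
        assert mean_curving_fixed_time(series, 50.0) == 0.0

    def test_fixed_time_constant_series_returns_constant(self):
        tr = make_circle_track(5.0, 0.5, 60.0)
        series = compute_curving(tr)
        assert mean_curving_fixed_time(series, 60.0) == pytest.approx(11.4591559, rel=1e-3)

    def test_fixed_time_window_too_long_raises_with_duration(self):
        series = compute_curving(make_straight_track(10.0))
        with pytest.raises(WormloopError, match="covers only"):
            mean_curving_fixed_time(series, 1200.0)

    def test_balanced_turns_average_to_zero(self):
        # equal path lengths at +10 and -10 deg/mm cancel in the weighted mean
        ds = 0.5
        rates = np.concatenate([np.full(30, 10.0), np.full(30, -10.0)])
        headings = np.radians(np.cumsum(rates * ds))
        x = np.concatenate([[0.0], np.cumsum(ds * np.cos(headings))])
        y = np.concatenate([[0.0], np.cumsum(ds * np.sin(headings))])
        tr = Trajectory("s-curve", np.arange(len(x), dtype=float), x, y, ventral_is_left=True)
        series = compute_curving(tr)
        # interior vertices see 29 steps at +10 and 30 at -10
        expected = np.average(rates[1:], weights=np.full(59, ds))
        assert mean_curving(series) == pytest.approx(expected, abs=1e-9)
        assert abs(mean_curving(series)) < 0.2

    def test_fixed_distance_straight_is_zero(self):
        assert mean_curving_fixed_distance(make_straight_track(50.0), 30.0) == 0.0

    def test_fixed_distance_constant_circle_equals_full_track_mean(self):
        tr = make_circle_track(5.0, 0.1, 40.0)
        fixed = mean_curving_fixed_distance(tr, 30.0)
        full = mean_curving(compute_curving(tr))
        assert fixed == pytest.approx(full, rel=1e-6)

    def test_fixed_distance_mixed_track_matches_oracle_on_truncation(self):
        # 20 mm straight then a tight loop; only the first 30 mm counts
        straight = make_straight_track(20.0, step_mm=0.5)
        loop = make_circle_track(
            2.0, 0.5, 25.0, start_angle_rad=-np.pi / 2, center=(20.0, 2.0)
        )
        tr = Trajectory(
            "mixed",
            np.arange(len(straight.t) + len(loop.t) - 1, dtype=float),
            np.concatenate([straight.x, loop.x[1:]]),
            np.concatenate([straight.y, loop.y[1:]]),
            ventral_is_left=True,
        )
        from wormloop import truncate_by_path_length

        expected_c, expected_w = brute_force_curving(truncate_by_path_length(tr, 30.0))
        assert mean_curving_fixed_distance(tr, 30.0, min_step_mm=0.0) == pytest.approx(
            np.average(expected_c, weights=expected_w), rel=1e-9
        )


class TestHistogram:
    def test_constant_series_in_single_bin(self):
        series = compute_curving(make_circle_track(5.0, 0.5, 30.0))
        hist = curving_histogram([series], bin_width_deg_per_mm=1.0)
        nonzero = hist[hist.weight_mm > 0]
        assert len(nonzero) == 1
        assert nonzero.bin_lo.iloc[0] == 11.0  # 11.459 falls in [11, 12)

    def test_mirror_pair_symmetric_and_mass_conserved(self):
        ccw = compute_curving(make_circle_track(5.0, 0.5, 30.0, ccw=True, ventral_is_left=None))
        cw = compute_curving(make_circle_track(5.0, 0.5, 30.0, ccw=False, ventral_is_left=None))
        hist = curving_histogram([ccw, cw], bin_width_deg_per_mm=1.0)
        nonzero = hist[hist.weight_mm > 0].reset_index(drop=True)
        assert len(nonzero) == 2
        np.testing.assert_allclose(nonzero.weight_mm[0], nonzero.weight_mm[1])
        assert hist.weight_mm.sum() == pytest.approx(
            ccw.step_lengths_mm.sum() + cw.step_lengths_mm.sum()
        )
        assert 0.0 in set(hist.bin_lo) | set(hist.bin_hi)  # zero is a bin edge

    def test_weights_match_direct_accumulation_oracle(self):
        s1 = compute_curving(
            simulate_trajectory(WalkConfig(noise_deg_per_mm_sd=8.0, duration_s=100, seed=1))
        )
        s2 = compute_curving(
            simulate_trajectory(WalkConfig(noise_deg_per_mm_sd=8.0, duration_s=60, seed=2))
        )
        w = 2.0
        hist = curving_histogram([s1, s2], w)
        values = np.concatenate([s1.curving_deg_per_mm, s2.curving_deg_per_mm])
        weights = np.concatenate([s1.step_lengths_mm, s2.step_lengths_mm])
        for _, row in hist.iterrows():
            mask = (values >= row.bin_lo) & (values < row.bin_hi)
            assert weights[mask].sum() == pytest.approx(row.weight_mm, abs=1e-9)

    def test_nonpositive_bin_width_rejected(self):
        series = compute_curving(make_straight_track(10.0))
        with pytest.raises(ParameterError):
            curving_histogram([series], 0.0)
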