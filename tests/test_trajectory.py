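"""Trajectory preprocessing, gait parameters, warping, and period statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon

from flynav import (
    AdvectionModel,
    StimulusSpec,
    Trajectory,
    TrialRejected,
    apply_exclusions,
    compute_gait,
    empirical_d_function,
    period_compare,
    preprocess,
    warp_to_odor_time,
)
from flynav.trajectory import signed_rank_test

FS = 50.0


def straight_walk(duration=20.0, speed=5.0, heading=30.0, fs=FS, start=(0.0, 10.0)):
    t = np.arange(int(duration * fs)) / fs
    h = np.deg2rad(heading)
    x = start[0] + speed * t * np.cos(h)
    y = start[1] + speed * t * np.sin(h)
    return t, x, y, np.full(t.size, float(heading))


class TestPreprocess:
    def test_straight_walk_passes_through(self):
        t, x, y, o = straight_walk()
        traj = preprocess(t, x, y, o)
        # zero-phase filtering leaves a straight constant-speed path intact
        np.testing.assert_allclose(traj.x, x, atol=0.1)
        np.testing.assert_allclose(traj.y, y, atol=0.1)
        np.testing.assert_allclose(np.mod(traj.heading, 360.0), 30.0, atol=1.0)

    def test_repairs_injected_orientation_flips(self):
        t, x, y, o = straight_walk()
        flipped = o.copy()
        flipped[300:500] = np.mod(flipped[300:500] + 180.0, 360.0)
        flipped[700:720] = np.mod(flipped[700:720] + 180.0, 360.0)
        traj = preprocess(t, x, y, flipped)
        np.testing.assert_allclose(np.mod(traj.heading, 360.0), 30.0, atol=2.0)

    def test_global_flip_resolved_by_travel_direction(self):
        t, x, y, o = straight_walk()
        traj = preprocess(t, x, y, np.mod(o + 180.0, 360.0))
        np.testing.assert_allclose(np.mod(traj.heading, 360.0), 30.0, atol=2.0)

    def test_filter_attenuates_high_frequency_noise(self, rng):
        t, x, y, o = straight_walk()
        wob = 1.0 * np.sin(2 * np.pi * 10.0 * t)  # 10 Hz >> 2.5 Hz cutoff
        traj = preprocess(t, x + wob, y, o)
        residual = traj.x - x
        assert np.std(residual[50:-50]) < 0.05 * np.std(wob)

    def test_rejects_short_paths(self):
        t, x, y, o = straight_walk(duration=20.0, speed=1.0)  # 20 mm total
        with pytest.raises(TrialRejected, match="25 mm"):
            preprocess(t, x, y, o)

    def test_rejects_tracking_gaps(self):
        t, x, y, o = straight_walk()
        t_gappy = t.copy()
        t_gappy[500:] += 0.5
        with pytest.raises(TrialRejected, match="gap"):
            preprocess(t_gappy, x, y, o)
        x_nan = x.copy()
        x_nan[100] = np.nan
        with pytest.raises(TrialRejected, match="missing"):
            preprocess(t, x_nan, y, o)


class TestComputeGait:
    def test_straight_walk_kinematics(self):
        t, x, y, o = straight_walk(speed=5.0, heading=90.0)
        gait = compute_gait(Trajectory(t, x, y, o))
        sl = slice(10, -10)
        np.testing.assert_allclose(gait.ground_speed[sl], 5.0, atol=1e-6)
        np.testing.assert_allclose(gait.upwind_velocity[sl], 5.0, atol=1e-6)
        np.testing.assert_allclose(gait.angular_velocity[sl], 0.0, atol=1e-9)
        assert np.all(gait.moving_mask)
        np.testing.assert_allclose(gait.turn_indicator[sl], 0.0)

    @pytest.mark.parametrize("radius", [2.0, 5.0])
    def test_circle_curvature_matches_geometry(self, radius):
        """Walking a circle of radius r gives curvature (180/pi)/r deg/mm."""
        speed = 6.0
        t = np.arange(int(30 * FS)) / FS
        omega = speed / radius  # rad/s
        x = radius * np.cos(omega * t)
        y = radius * np.sin(omega * t)
        heading = np.rad2deg(omega * t) + 90.0
        gait = compute_gait(Trajectory(t, x, y, heading))
        sl = slice(10, -10)
        expected = np.rad2deg(1.0) / radius
        np.testing.assert_allclose(gait.curvature[sl], expected, rtol=1e-3)
        # turning iff curvature above 20 deg/mm, i.e. radius below ~2.86 mm
        expected_turn = 1.0 if expected > 20.0 else 0.0
        np.testing.assert_allclose(gait.turn_indicator[sl], expected_turn)

    def test_stationary_samples_masked(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.zeros(t.size)
        y = np.zeros(t.size)
        gait = compute_gait(Trajectory(t, x, y, np.zeros(t.size)))
        assert not gait.moving_mask.any()
        assert np.all(np.isnan(gait.curvature))
        assert np.all(np.isnan(gait.turn_indicator))


class TestWarpToOdorTime:
    def test_stationary_fly_gets_constant_shift(self):
        t, x, y, o = straight_walk(duration=70.0, speed=0.0, start=(0.0, 21.0))
        traj = Trajectory(t, x, y, o)
        gait = compute_gait(traj)
        gait.ground_speed[:] = np.arange(t.size, dtype=float)  # a recognizable ramp
        spec = StimulusSpec("square_pulse", onset=10.0, duration=10.0)
        adv = AdvectionModel(wind_speed=119.0)
        warped = warp_to_odor_time(gait, traj, spec, adv)
        shift = int(round((140.0 - 21.0) / 119.0 * FS))
        sl = slice(100, 3000)
        np.testing.assert_allclose(
            warped.ground_speed[np.arange(t.size)[sl] - shift],
            gait.ground_speed[sl],
        )

    def test_preserves_time_axis_and_shapes(self):
        t, x, y, o = straight_walk(duration=70.0, speed=2.0, heading=90.0)
        traj = Trajectory(t, x, y, o)
        gait = compute_gait(traj)
        spec = StimulusSpec("square_pulse", onset=10.0, duration=10.0)
        warped = warp_to_odor_time(gait, traj, spec, AdvectionModel())
        assert warped.ground_speed.shape == gait.ground_speed.shape
        np.testing.assert_allclose(warped.t, gait.t)

    def test_warped_values_come_from_original_series(self):
        t, x, y, o = straight_walk(duration=70.0, speed=2.0, heading=90.0)
        traj = Trajectory(t, x, y, o)
        gait = compute_gait(traj)
        spec = StimulusSpec("square_pulse", onset=10.0, duration=10.0)
        warped = warp_to_odor_time(gait, traj, spec, AdvectionModel())
        finite = np.isfinite(warped.upwind_velocity)
        assert np.all(np.isin(
            np.round(warped.upwind_velocity[finite], 9),
            np.round(gait.upwind_velocity, 9),
        ))


class TestApplyExclusions:
    def test_wall_margin_excluded(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.linspace(0.0, 19.0, t.size)  # drifts toward the +x wall
        y = np.full(t.size, 50.0)
        traj = Trajectory(t, x, y, np.zeros(t.size))
        gait = compute_gait(traj)
        out = apply_exclusions(gait, traj)
        near_wall = x > 17.0
        assert not out.valid_mask[near_wall].any()
        assert out.valid_mask[~near_wall].all()

    def test_samples_after_reaching_top_excluded(self):
        t, x, y, o = straight_walk(duration=40.0, speed=5.0, heading=90.0, start=(0.0, 0.0))
        traj = Trajectory(t, x, y, o)
        gait = compute_gait(traj)
        out = apply_exclusions(gait, traj)
        reach = np.argmax(y >= 139.0)
        assert not out.valid_mask[reach:].any()
        assert out.valid_mask[:reach].all()


class TestSignedRankTest:
    def test_exact_small_sample_matches_enumeration(self, rng):
        """Brute-force sign-flip enumeration reproduces the exact p-value."""
        d = rng.normal(0.5, 1.0, 8)
        d = d[d != 0]
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=d.size):
            s = np.asarray(signs, dtype=bool)
            w = min(ranks[s].sum(), ranks[~s].sum())
            if w <= w_obs:
                count += 1
        p_brute = count / 2 ** d.size
        assert signed_rank_test(d, np.zeros(d.size)) == pytest.approx(p_brute)

    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        assert signed_rank_test(x, x) == 1.0

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(0.2, 1.0, 100)
        p = signed_rank_test(x, np.zeros(100))
        ref = wilcoxon(x, method="approx", correction=True).pvalue
        assert p == pytest.approx(float(ref))


class TestPeriodCompare:
    def test_detects_step_change_across_flies(self, rng):
        t = np.arange(int(70 * FS)) / FS
        series = []
        for _ in range(12):
            v = rng.normal(0.0, 0.2, t.size)
            v[(t >= 10.0) & (t < 20.0)] += 3.0  # clear during-odor elevation
            series.append(v)
        stats = period_compare(t, series, onset=10.0)
        assert stats.p_values["before-during"] < stats.alpha_corrected
        assert stats.significant["before-during"]
        assert stats.alpha_corrected == pytest.approx(0.05 / 3)
        assert stats.per_fly_means.shape == (12, 3)

    def test_moving_mask_restricts_the_means(self):
        t = np.arange(int(70 * FS)) / FS
        series = [np.where(t < 35.0, 1.0, 100.0) for _ in range(6)]
        moving = [t < 35.0 for _ in range(6)]
        stats = period_compare(t, series, moving, onset=10.0)
        np.testing.assert_allclose(stats.per_fly_means[:, :2], 1.0)

    def test_requires_five_flies(self):
        t = np.arange(int(70 * FS)) / FS
        with pytest.raises(ValueError, match="5 flies"):
            period_compare(t, [np.zeros(t.size)] * 4, onset=10.0)


class TestEmpiricalDFunction:
    def test_constant_rotation_recovered_in_all_bins(self):
        t = np.arange(int(60 * FS)) / FS
        heading = 30.0 * t  # constant 30 deg/s rotation sweeps all wind angles
        traj = Trajectory(t, np.zeros(t.size), np.zeros(t.size), heading)
        centers, d = empirical_d_function(traj)
        assert centers.size == 18
        np.testing.assert_allclose(d, 30.0, atol=1e-6)
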