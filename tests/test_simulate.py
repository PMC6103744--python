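"""Navigation simulator: baseline contracts, wind steering, bilateral sensing."""

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pytest

from flynav import (
    NavParams,
    StimulusSpec,
    make_arena_env,
    run_ensemble,
    simulate_trial,
    wind_angle,
)

FS = 50.0


@dataclass
class UniformEnvironment:
    """Spatially uniform, constant-in-time concentration; optional wind."""

    level: float = 0.0
    wind_upwind_deg: Optional[float] = None
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((-500.0, 500.0), (-500.0, 500.0))
    duration: float = 60.0

    def concentration(self, x, y, t):
        return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, self.level)


@dataclass
class LateralGradientEnvironment:
    """Concentration increasing linearly with x; no wind."""

    slope: float = 0.001
    offset: float = 0.5
    wind_upwind_deg: Optional[float] = None
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((-500.0, 500.0), (-500.0, 500.0))
    duration: float = 10.0

    def concentration(self, x, y, t):
        return np.broadcast_to(
            self.offset + self.slope * np.asarray(x, dtype=float),
            np.broadcast(np.asarray(x), np.asarray(y)).shape,
        ).copy()


class TestWindAngle:
    def test_zero_when_facing_upwind(self):
        assert wind_angle(90.0, 90.0) == 0.0

    def test_wraps_to_half_open_interval(self):
        assert wind_angle(-90.0, 90.0) == 180.0
        assert wind_angle(270.0, 90.0) == 180.0
        assert wind_angle(100.0, 90.0) == pytest.approx(-10.0)

    def test_raises_without_wind(self):
        with pytest.raises(ValueError, match="no-wind"):
            wind_angle(0.0, None)


class TestBaselineContracts:
    def test_speed_exactly_baseline_without_odor(self):
        env = UniformEnvironment(level=0.0)
        res = run_ensemble(env, NavParams(), 20, seed=0, duration=30.0)
        assert np.all(res.speed == 6.0)
        assert np.all(res.on == 0.0)
        assert np.all(res.off == 0.0)
        assert np.all(res.odor == 0.0)

    def test_turn_probability_is_baseline_without_odor(self):
        env = UniformEnvironment(level=0.0)
        res = run_ensemble(env, NavParams(), 10, seed=0, duration=10.0)
        assert np.all(res.turn_prob == 0.12)

    def test_empirical_turn_rate_matches_baseline(self):
        """Fraction of samples with a random turn approximates p0 = 0.12."""
        env = UniformEnvironment(level=0.0)
        res = run_ensemble(env, NavParams(), 300, seed=7, duration=70.0)
        turned = np.diff(res.heading, axis=1) != 0.0
        n = turned.size
        assert n >= 1_000_000
        rate = turned.mean()
        se = np.sqrt(0.12 * 0.88 / n)
        assert se < 0.0005
        assert abs(rate - 0.12) < 5 * se

    def test_rate_conversion_preserves_turn_probability_per_time(self):
        """At 15 Hz the per-sample probability scales by dt / 20 ms."""
        env = UniformEnvironment(level=0.0)
        res = run_ensemble(env, NavParams(dt=1.0 / 15), 10, seed=0, duration=10.0)
        assert np.allclose(res.turn_prob, 0.12 * (1.0 / 15) / 0.02)

    def test_heavy_tailed_turn_amplitudes(self):
        """Squaring the Gaussian draw produces occasional very large turns."""
        env = UniformEnvironment(level=0.0)
        res = run_ensemble(env, NavParams(), 100, seed=3, duration=60.0)
        dh = np.abs(np.diff(res.heading, axis=1)) / NavParams().dt  # deg/s
        dh = dh[dh > 0]
        assert np.percentile(dh, 95) > 3 * np.median(dh)


class TestDeterminismAndScales:
    def test_same_seed_reproduces_trajectories(self):
        env = UniformEnvironment(level=0.2)
        a = run_ensemble(env, NavParams(), 5, seed=11, duration=10.0)
        b = run_ensemble(env, NavParams(), 5, seed=11, duration=10.0)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.heading, b.heading)

    def test_different_seeds_differ(self):
        env = UniformEnvironment(level=0.2)
        a = run_ensemble(env, NavParams(), 5, seed=11, duration=10.0)
        b = run_ensemble(env, NavParams(), 5, seed=12, duration=10.0)
        assert not np.array_equal(a.heading, b.heading)

    def test_zero_trials_returns_none(self):
        assert run_ensemble(UniformEnvironment(), NavParams(), 0) is None

    def test_on_scale_modulates_speed(self):
        env = UniformEnvironment(level=1.0)
        lo = run_ensemble(env, NavParams(on_scale=0.5), 20, seed=0, duration=40.0)
        hi = run_ensemble(env, NavParams(on_scale=2.0), 20, seed=0, duration=40.0)
        assert hi.speed[:, -1].mean() > lo.speed[:, -1].mean()

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="probability"):
            NavParams(p0=1.5)
        with pytest.raises(ValueError, match="kappa2"):
            NavParams(kappa2=-1.0)
        with pytest.raises(ValueError, match="dt"):
            NavParams(dt=0.0)


class TestSimulateTrial:
    def test_returns_trajectory_and_states(self):
        env = UniformEnvironment(level=0.1, wind_upwind_deg=90.0)
        traj, states = simulate_trial(env, NavParams(), init=(0.0, 0.0, 45.0), seed=1, duration=20.0)
        assert len(traj) == int(round(20.0 / 0.02))
        assert set(states) == {"odor", "on", "off", "turn_prob", "speed"}
        assert states["on"].value.max() > 0.0

    def test_rejects_initial_position_outside_bounds(self):
        env = UniformEnvironment()
        with pytest.raises(ValueError, match="bounds"):
            simulate_trial(env, NavParams(), init=(1000.0, 0.0, 0.0))

    def test_positions_stay_within_bounds(self):
        env = UniformEnvironment(level=0.0, bounds=((-10.0, 10.0), (-10.0, 10.0)), duration=30.0)
        res = run_ensemble(env, NavParams(), 20, seed=2)
        assert res.x.min() >= -10.0 and res.x.max() <= 10.0
        assert res.y.min() >= -10.0 and res.y.max() <= 10.0


class TestWindSteering:
    def test_odor_pulse_drives_upwind_surge(self, square_pulse_spec):
        """Mean upwind velocity rises during odor relative to before."""
        env = make_arena_env(square_pulse_spec)
        res = run_ensemble(env, NavParams(), 200, seed=0, duration=40.0, init_rule="uniform")
        v = res.upwind_velocity()
        before = v[:, (res.t >= 2.0) & (res.t < 10.0)].mean()
        during = v[:, (res.t >= 13.0) & (res.t < 20.0)].mean()
        assert during > before + 2.0

    def test_wind_blind_model_shows_no_upwind_modulation(self, square_pulse_spec):
        env = make_arena_env(square_pulse_spec)
        p = NavParams(kappa5=0.0, kappa6=0.0)
        res = run_ensemble(env, p, 200, seed=0, duration=40.0, init_rule="uniform")
        v = res.upwind_velocity()
        before = v[:, (res.t >= 2.0) & (res.t < 10.0)].mean()
        during = v[:, (res.t >= 13.0) & (res.t < 20.0)].mean()
        assert abs(during - before) < 1.0

    def test_baseline_ensemble_drifts_downwind(self):
        """With no odor the weak constant drive orients flies downwind."""
        env = make_arena_env(StimulusSpec("constant_zero"))
        res = run_ensemble(env, NavParams(), 200, seed=4, duration=60.0, init_rule="uniform")
        assert res.y[:, -1].mean() < res.y[:, 0].mean() - 5.0


class TestBilateralSensing:
    def test_uniform_field_gives_no_bilateral_drive(self):
        """With equal antennal inputs, swapping the antennae changes nothing."""
        env = UniformEnvironment(level=0.5)
        a = run_ensemble(env, NavParams(kappa7=300.0), 10, seed=5, duration=20.0)
        b = run_ensemble(env, NavParams(kappa7=300.0, swap_antennae=True), 10, seed=5, duration=20.0)
        np.testing.assert_array_equal(a.heading, b.heading)

    def test_turns_toward_higher_concentration(self):
        """Facing +y in a rightward gradient, the right antenna reads more
        odor, so the bilateral term steers clockwise (toward the odor)."""
        env = LateralGradientEnvironment()
        p = NavParams(p0=0.0, kappa7=300.0)  # no random turns, no wind terms
        traj, _ = simulate_trial(env, p, init=(0.0, 0.0, 90.0), seed=0, duration=5.0)
        assert traj.heading[-1] < 90.0

    def test_swapped_antennae_reverse_the_turn(self):
        env = LateralGradientEnvironment()
        p = NavParams(p0=0.0, kappa7=300.0, swap_antennae=True)
        traj, _ = simulate_trial(env, p, init=(0.0, 0.0, 90.0), seed=0, duration=5.0)
        assert traj.heading[-1] > 90.0

    def test_nan_concentration_raises(self):
        @dataclass
        class NaNEnv:
            wind_upwind_deg: Optional[float] = None
            bounds: Tuple = ((-10.0, 10.0), (-10.0, 10.0))
            duration: float = 1.0

            def concentration(self, x, y, t):
                return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, np.nan)

        with pytest.raises(ValueError, match="NaN"):
            run_ensemble(NaNEnv(), NavParams(), 2, seed=0)
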