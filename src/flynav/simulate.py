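"""Stochastic wind-guided navigation agent driven by ON and OFF odor responses.

Each model fly carries the ON and OFF response models as internal state
(adaptive compression plus filtering, integrated by forward Euler alongside
the walk).  Per time step:

    speed          v = max(0, v0 + k1*ON - k2*OFF)
    turn prob.     P = clip(P0 - k3*ON + k4*OFF, 0, 1)        (per sample)
    ang. velocity  dH = rho * sign(g) * g^2 * dt               (random turns)
                      + [k5*ON*sin(psi) - k6*sin(psi)] * r     (wind steering)
                      + k7*(CL - CR) * dt                      (bilateral)

with rho ~ Bernoulli(P), g ~ Normal(0, sigma), psi the signed angle from the
fly's heading to the upwind direction, and r = dt/0.02 the per-sample rate
conversion (simulations in plume movies run at the movie frame rate of
15 Hz; all per-sample coefficients are rescaled so rates per unit time are
preserved).  The squared Gaussian draw (sigma = 20 deg/s gives typical turn
rates of several hundred deg/s) yields the heavy-tailed angular-velocity
distribution of real flies; the sign is re-attached so turns go both ways.
Positions update as X += dt v cos(H), Y += dt v sin(H), clamped to the
environment bounds with heading unchanged.

The upwind drive stabilizes psi = 0: a heading increment of +k5*ON*sin(psi)
changes psi by -k5*ON*sin(psi), a restoring force toward upwind.  The weak
constant downwind drive -k6*sin(psi) correspondingly stabilizes psi = 180.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Tuple

import numpy as np

from .response import KD_BASELINE, TABLE_OFF, TABLE_ON
from .signals import SignalTrace
from .trajectory import Trajectory

__all__ = [
    "NavParams",
    "Environment",
    "wind_angle",
    "EnsembleResult",
    "simulate_trial",
    "run_ensemble",
]

BASE_DT = 0.02  # s; the sampling the per-sample coefficients were defined at


class Environment(Protocol):
    """A queryable odor world: concentration field, wind, bounds, duration."""

    wind_upwind_deg: Optional[float]  # direction the wind blows FROM; None = no wind
    bounds: Tuple[Tuple[float, float], Tuple[float, float]]  # (x range, y range), mm
    duration: float  # s

    def concentration(self, x: np.ndarray, y: np.ndarray, t: float) -> np.ndarray:
        ...


@dataclass
class NavParams:
    """Navigation-model parameters (defaults are the published fitted values)."""

    v0: float = 6.0  # mm/s baseline ground speed
    p0: float = 0.12  # baseline turn probability per 20-ms sample
    sigma: float = 20.0  # deg/s, SD of the random angular-velocity draw
    kappa1: float = 0.45  # mm/s, ON speed modulation
    kappa2: float = 0.8  # mm/s, OFF speed modulation
    kappa3: float = 0.03  # ON turn-probability modulation
    kappa4: float = 0.75  # OFF turn-probability modulation
    kappa5: float = 5.0  # deg/sample, ON-gated upwind drive
    kappa6: float = 0.5  # deg/sample, constant downwind drive
    kappa7: float = 0.0  # deg/s per unit compressed-concentration difference
    on_scale: float = 1.0  # per-fly multiplier on the ON function
    off_scale: float = 1.0  # per-fly multiplier on the OFF function
    dt: float = BASE_DT  # s (1/15 for plume-movie simulations)
    antenna_offset: float = 0.74  # mm, right-antenna sampling offset
    swap_antennae: bool = False  # interpret left as right and vice versa
    kd: float = KD_BASELINE
    # ON/OFF model time constants (published ACF fits)
    tau_on: float = TABLE_ON["ACF"]["tau_on"]
    tau_a_on: float = TABLE_ON["ACF"]["tau_a"]
    tau_off1: float = TABLE_OFF["ACF"]["tau_off1"]
    tau_off2: float = TABLE_OFF["ACF"]["tau_off2"]
    tau_a_off: float = TABLE_OFF["ACF"]["tau_a"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be a probability")
        for name in ("kappa1", "kappa2", "kappa3", "kappa4", "kappa5", "kappa6", "kappa7"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def wind_angle(heading_deg, wind_upwind_deg: Optional[float]):
    """Signed angle psi from the fly's heading to the upwind direction.

    Wrapped to (-180, 180]; psi = 0 means the fly faces exactly upwind.
    Raises if the environment has no wind (the wind terms must then be
    forced to zero by the caller).
    """
    if wind_upwind_deg is None:
        raise ValueError("psi undefined in a no-wind environment")
    a = np.asarray(wind_upwind_deg - np.asarray(heading_deg, dtype=float))
    return -np.mod(-a + 180.0, 360.0) + 180.0


@dataclass
class EnsembleResult:
    """Trajectories and model-state traces of a batch of simulated trials.

    Arrays are shaped (n_trials, n_steps); ``t`` is the shared clock.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    on: np.ndarray
    off: np.ndarray
    odor: np.ndarray
    turn_prob: np.ndarray  # theoretical P(t), already clipped
    speed: np.ndarray  # commanded ground speed v(t), mm/s
    params: NavParams = field(repr=False, default=None)

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]

    def trajectory(self, i: int, sample_rate: Optional[float] = None,
                   arena: Optional[tuple] = None) -> Trajectory:
        fs = 1.0 / self.params.dt if sample_rate is None else sample_rate
        kw = {} if arena is None else {"arena": arena}
        return Trajectory(self.t, self.x[i], self.y[i], self.heading[i], fs, **kw)

    def upwind_velocity(self) -> np.ndarray:
        """Per-trial dY/dt (mm/s), shaped like the state arrays."""
        dt = self.t[1] - self.t[0]
        v = np.gradient(self.y, dt, axis=1)
        return v


def _simulate_batch(
    env: Environment,
    p: NavParams,
    init_xy: np.ndarray,
    init_heading: np.ndarray,
    rng: np.random.Generator,
    duration: Optional[float] = None,
    on_scale: Optional[np.ndarray] = None,
    off_scale: Optional[np.ndarray] = None,
) -> EnsembleResult:
    """Advance a batch of independent agents through the environment.

    ``on_scale``/``off_scale`` may be per-agent arrays overriding the scalar
    scales in ``p`` (used for across-fly variability).
    """
    n = init_xy.shape[0]
    on_sc = p.on_scale if on_scale is None else np.asarray(on_scale, dtype=float)
    off_sc = p.off_scale if off_scale is None else np.asarray(off_scale, dtype=float)
    dt = p.dt
    duration = env.duration if duration is None else duration
    n_steps = int(round(duration / dt))
    rate = dt / BASE_DT  # per-sample rate conversion

    (xmin, xmax), (ymin, ymax) = env.bounds
    x = init_xy[:, 0].astype(float).copy()
    y = init_xy[:, 1].astype(float).copy()
    H = init_heading.astype(float).copy()

    a_on = dt / p.tau_a_on
    a_f = dt / p.tau_on
    a_off = dt / p.tau_a_off
    a_r1 = dt / p.tau_off1
    a_r2 = dt / p.tau_off2

    A_on = np.zeros(n)
    ON = np.zeros(n)
    A_off = np.zeros(n)
    R1 = np.zeros(n)
    R2 = np.zeros(n)

    out = {
        k: np.empty((n, n_steps))
        for k in ("x", "y", "heading", "on", "off", "odor", "turn_prob", "speed")
    }
    t_axis = np.arange(n_steps) * dt
    has_wind = env.wind_upwind_deg is not None
    bilateral = p.kappa7 > 0

    for k in range(n_steps):
        t = t_axis[k]
        odor = np.asarray(env.concentration(x, y, t), dtype=float)
        if np.any(np.isnan(odor)):
            raise ValueError("environment returned NaN concentration")

        OFF = np.maximum(0.0, R2 - R1)
        on_eff = on_sc * ON
        off_eff = off_sc * OFF

        v = np.maximum(0.0, p.v0 + p.kappa1 * on_eff - p.kappa2 * off_eff)
        P = np.clip((p.p0 - p.kappa3 * on_eff + p.kappa4 * off_eff) * rate, 0.0, 1.0)

        rho = rng.random(n) < P
        g = rng.normal(0.0, p.sigma, n)
        dH = rho * np.sign(g) * g**2 * dt
        if has_wind:
            psi = np.deg2rad(wind_angle(H, env.wind_upwind_deg))
            dH = dH + (p.kappa5 * on_eff - p.kappa6) * np.sin(psi) * rate
        if bilateral:
            hr = np.deg2rad(H)
            xr = x + p.antenna_offset * np.sin(hr)
            yr = y - p.antenna_offset * np.cos(hr)
            odor_r = np.asarray(env.concentration(xr, yr, t), dtype=float)
            CL = odor / (odor + p.kd + A_on)
            CR = odor_r / (odor_r + p.kd + A_on)
            if p.swap_antennae:
                CL, CR = CR, CL
            dH = dH + p.kappa7 * (CL - CR) * dt

        out["x"][:, k] = x
        out["y"][:, k] = y
        out["heading"][:, k] = H
        out["on"][:, k] = ON
        out["off"][:, k] = OFF
        out["odor"][:, k] = odor
        out["turn_prob"][:, k] = P
        out["speed"][:, k] = v

        hrad = np.deg2rad(H)
        x = np.clip(x + dt * v * np.cos(hrad), xmin, xmax)
        y = np.clip(y + dt * v * np.sin(hrad), ymin, ymax)
        H = H + dH

        # advance the sensory states (forward Euler, matching the response
        # models' one-sample input delay)
        C_on = odor / (odor + p.kd + A_on)
        C_off = odor / (odor + p.kd + A_off)
        ON += a_f * (C_on - ON)
        R1 += a_r1 * (C_off - R1)
        R2 += a_r2 * (C_off - R2)
        A_on += a_on * (odor - A_on)
        A_off += a_off * (odor - A_off)

    return EnsembleResult(t=t_axis, params=p, **out)


def _default_inits(
    env: Environment, n: int, rng: np.random.Generator, rule: str
) -> Tuple[np.ndarray, np.ndarray]:
    (xmin, xmax), (ymin, ymax) = env.bounds
    if rule == "uniform":
        ylo, yhi = ymin, ymax
    elif rule == "downwind_quarter":
        ylo, yhi = ymin, ymin + 0.25 * (ymax - ymin)
    else:
        raise ValueError(f"unknown init rule {rule!r}")
    xy = np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ylo, yhi, n)]
    )
    heading = rng.uniform(0.0, 360.0, n)
    return xy, heading


def simulate_trial(
    env: Environment,
    p: NavParams,
    init: Optional[Tuple[float, float, float]] = None,
    seed: int = 0,
    duration: Optional[float] = None,
):
    """One seeded trial; returns (Trajectory, state dict of SignalTraces).

    ``init`` is (x, y, heading); if omitted, the position is drawn uniformly
    in the downwind quarter of the domain with a uniform random heading.
    """
    rng = np.random.default_rng(seed)
    if init is None:
        xy, h = _default_inits(env, 1, rng, "downwind_quarter")
    else:
        xy = np.array([[init[0], init[1]]], dtype=float)
        h = np.array([init[2]], dtype=float)
        (xmin, xmax), (ymin, ymax) = env.bounds
        if not (xmin <= init[0] <= xmax and ymin <= init[1] <= ymax):
            raise ValueError("initial position outside environment bounds")
    res = _simulate_batch(env, p, xy, h, rng, duration)
    fs = 1.0 / p.dt
    traj = res.trajectory(0)
    states = {
        name: SignalTrace(res.t, getattr(res, name)[0], fs)
        for name in ("odor", "on", "off", "turn_prob", "speed")
    }
    return traj, states


def run_ensemble(
    env: Environment,
    p: NavParams,
    n_trials: int,
    seed: int = 0,
    init_rule: str = "downwind_quarter",
    duration: Optional[float] = None,
    scale_table: Optional[np.ndarray] = None,
) -> Optional[EnsembleResult]:
    """A seeded batch of independent trials.

    ``scale_table`` is an optional (m, 2) array of per-fly (ON, OFF) scale
    pairs; each trial draws one pair at random, emulating across-fly
    variability.  Returns None for ``n_trials == 0``.
    """
    if n_trials == 0:
        return None
    rng = np.random.default_rng(seed)
    xy, h = _default_inits(env, n_trials, rng, init_rule)
    if scale_table is None:
        return _simulate_batch(env, p, xy, h, rng, duration)
    scale_table = np.asarray(scale_table, dtype=float)
    picks = rng.integers(0, scale_table.shape[0], n_trials)
    return _simulate_batch(
        env, p, xy, h, rng, duration,
        on_scale=scale_table[picks, 0], off_scale=scale_table[picks, 1],
    )
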