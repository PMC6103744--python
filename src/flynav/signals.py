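"""Odor stimulus waveforms and their transport down the arena.

Concentrations are dimensionless, normalized so that 1.0 corresponds to the
strongest stimulus used in the behavioral experiments (10% apple cider
vinegar).  All traces live on a uniform time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SignalTrace",
    "StimulusSpec",
    "AdvectionModel",
    "make_stimulus",
    "advect",
    "extract_plume_walk",
]

_GRID_TOL = 1e-9  # seconds; allowed deviation from a uniform grid

STIMULUS_KINDS = (
    "square_pulse",
    "off_ramp",
    "freq_sweep_up",
    "freq_sweep_down",
    "plume_walk",
    "constant_zero",
)


@dataclass
class SignalTrace:
    """A uniformly sampled, non-negative concentration (or model-state) trace."""

    t: np.ndarray
    value: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same shape")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - dt[0]) > _GRID_TOL):
                raise ValueError("time grid is not uniform")
            if abs(self.sample_rate * dt[0] - 1.0) > 1e-6:
                raise ValueError("sample_rate inconsistent with time grid")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def __len__(self) -> int:
        return self.t.size

    def copy_with(self, value: np.ndarray) -> "SignalTrace":
        return SignalTrace(self.t.copy(), np.asarray(value, dtype=float), self.sample_rate)

    def to_csv(self, path) -> None:
        """Write as 2-column CSV (t_s, concentration_norm)."""
        import pandas as pd

        pd.DataFrame({"t_s": self.t, "concentration_norm": self.value}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SignalTrace":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(float)
        rate = 1.0 / (t[1] - t[0])
        return cls(t, df["concentration_norm"].to_numpy(float), round(rate, 9))


@dataclass
class StimulusSpec:
    """Declarative description of one open-loop odor stimulus.

    ``concentration`` is the peak normalized concentration.  Frequency sweeps
    are raised sinusoids from 0 to ``concentration`` whose instantaneous
    frequency moves linearly in time across ``freq_range``.  The off-ramp
    holds its peak for ``plateau`` seconds and then descends linearly to zero
    over ``ramp_duration``.
    """

    kind: str
    concentration: float = 1.0
    onset: float = 10.0
    duration: float = 10.0
    ramp_duration: float = 10.0
    plateau: float = 10.0
    freq_range: tuple = (0.1, 1.0)
    trial_length: float = 70.0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.kind in ("freq_sweep_up", "freq_sweep_down"):
            lo, hi = min(self.freq_range), max(self.freq_range)
            if lo < 0.05 or hi > 1.5:
                raise ValueError("freq_range outside the deliverable 0.05-1.5 Hz band")
        total = self.onset + self.duration
        if self.kind == "off_ramp":
            total = self.onset + self.plateau + self.ramp_duration
        if total > self.trial_length + 1e-9:
            raise ValueError("stimulus extends beyond trial_length")


@dataclass
class AdvectionModel:
    """Transport of the odor waveform down the arena by laminar airflow.

    ``wind_speed`` defaults to the measured arena flow of 11.9 cm/s.  A
    positive ``diffusion_widening`` (seconds of Gaussian smoothing per cm of
    travel) emulates the observed broadening of stimulus peaks with distance
    downwind; the default of zero gives ideal (pure-delay) transport.
    """

    wind_speed: float = 119.0  # mm/s
    diffusion_widening: float = 0.0  # s per cm of travel

    def __post_init__(self) -> None:
        if self.wind_speed <= 0:
            raise ValueError("wind_speed must be positive")


def make_stimulus(spec: StimulusSpec, sample_rate: float, movie=None) -> SignalTrace:
    """Render a stimulus spec to a concentration trace.

    ``kind="plume_walk"`` requires a plume ``movie``; the trace is then the
    default upwind transect through it (see :func:`extract_plume_walk`),
    zero-padded to ``trial_length``.
    """
    n = int(round(spec.trial_length * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.zeros(n)
    c = spec.concentration

    if spec.kind == "constant_zero":
        pass
    elif spec.kind == "square_pulse":
        on = (t >= spec.onset) & (t < spec.onset + spec.duration)
        v[on] = c
    elif spec.kind == "off_ramp":
        hold = (t >= spec.onset) & (t < spec.onset + spec.plateau)
        v[hold] = c
        t0 = spec.onset + spec.plateau
        ramp = (t >= t0) & (t < t0 + spec.ramp_duration)
        v[ramp] = c * (1.0 - (t[ramp] - t0) / spec.ramp_duration)
    elif spec.kind in ("freq_sweep_up", "freq_sweep_down"):
        f0, f1 = spec.freq_range
        if spec.kind == "freq_sweep_down":
            f0, f1 = f1, f0
        on = (t >= spec.onset) & (t < spec.onset + spec.duration)
        tau = t[on] - spec.onset
        # phase = integral of the linearly varying instantaneous frequency
        phase = f0 * tau + 0.5 * (f1 - f0) * tau**2 / spec.duration
        v[on] = c * 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    elif spec.kind == "plume_walk":
        if movie is None:
            raise ValueError("plume_walk stimulus requires a plume movie")
        walk = extract_plume_walk(movie)
        walk_n = min(len(walk), n)
        # resample the movie-rate transect onto the requested grid
        v[:walk_n] = np.interp(
            t[:walk_n], walk.t, walk.value, left=0.0, right=0.0
        )
    return SignalTrace(t, v, sample_rate)


def sweep_phase(spec: StimulusSpec, tau: np.ndarray) -> np.ndarray:
    """Closed-form phase integral of a sweep at times ``tau`` after onset."""
    f0, f1 = spec.freq_range
    if spec.kind == "freq_sweep_down":
        f0, f1 = f1, f0
    return f0 * tau + 0.5 * (f1 - f0) * tau**2 / spec.duration


def advect(trace: SignalTrace, distance_downwind: float, model: AdvectionModel) -> SignalTrace:
    """Delay (and optionally smooth) a waveform transported ``distance_downwind`` mm.

    The delay is ``distance / wind_speed``; sub-sample delays are realized by
    linear interpolation onto the original grid, so the output stays on the
    same uniform grid as the input.
    """
    if distance_downwind < 0:
        raise ValueError("distance_downwind must be non-negative")
    delay = distance_downwind / model.wind_speed
    if delay == 0.0 and model.diffusion_widening == 0.0:
        return trace.copy_with(trace.value.copy())
    shifted = np.interp(trace.t - delay, trace.t, trace.value, left=0.0, right=0.0)
    if model.diffusion_widening > 0:
        sigma_s = model.diffusion_widening * distance_downwind / 10.0
        sigma_samples = sigma_s * trace.sample_rate
        if sigma_samples > 0:
            shifted = gaussian_filter1d(shifted, sigma_samples, mode="constant")
    return trace.copy_with(shifted)


def extract_plume_walk(
    movie,
    start_lateral: float = 89.0,
    start_downwind: float = 300.0,
    speed: float = 6.0,
) -> SignalTrace:
    """Concentration along a straight upwind transect through a plume movie.

    A virtual point starts ``start_downwind`` mm downwind of the source and
    ``start_lateral`` mm off the midline and moves straight upwind at walking
    ``speed`` (mm/s); the concentration under it is sampled once per movie
    frame until the point reaches the source plane or leaves the domain.
    """
    fps = movie.fps
    n_frames = int(np.floor(start_downwind / speed * fps))
    x_src, y_src = movie.source_xy
    x = x_src - start_lateral  # lateral offset, arena frame
    # The historical transect started marginally outside the imaged width
    # (8.9 cm lateral vs 8 cm imaged), so allow a small lateral overshoot
    # where the concentration is simply zero.
    if start_downwind > movie.downwind_extent + movie.px_mm:
        raise ValueError("plume-walk start point outside movie domain (downwind)")
    if start_lateral > movie.lateral_half_width + 15.0:
        raise ValueError("plume-walk start point outside movie domain (lateral)")
    t = np.arange(n_frames) / fps
    y = (y_src - start_downwind) + speed * t  # moving upwind toward the source
    conc = movie.at(np.full(n_frames, x), y, t)
    return SignalTrace(t, conc, fps)
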