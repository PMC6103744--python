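"""Synthetic odor environments: arena stimuli, a kinematic puff plume, and
a windless Gaussian gradient; plus a generator of synthetic behavioral data.

The puff plume is a desk-scale kinematic emulation of a measured turbulent
boundary-layer plume: Gaussian odor puffs are released at the source, advect
downwind at the mean flow speed, widen linearly with travel, decay in
amplitude with an e-folding length, and ride a slowly meandering centerline
(a mean-reverting random walk).  It reproduces the qualitative structure of
such plumes (centerline concentration maximum, monotone downwind decay,
intermittency at the edges) without any fluid dynamics.

World frame: y increases upwind, the wind blows toward -y, the plume source
sits at the upwind end of its domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .signals import AdvectionModel, SignalTrace, StimulusSpec, make_stimulus

__all__ = [
    "PlumeMovie",
    "PlumeGenParams",
    "make_synthetic_plume",
    "intermittency_map",
    "ArenaEnvironment",
    "make_arena_env",
    "PlumeEnvironment",
    "GradientEnvironment",
    "make_synthetic_behavior",
]


@dataclass
class PlumeMovie:
    """A space-time concentration field normalized to the source pixel.

    ``frames`` is (T, Y, X) with the y axis ascending toward the source
    (upwind); ``source_xy`` is the source position in world coordinates.
    """

    frames: np.ndarray  # (T, Y, X), float32, >= 0
    px_mm: float = 0.74
    fps: float = 15.0
    source_xy: Tuple[float, float] = (0.0, 300.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, Y, X)")

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.fps

    @property
    def downwind_extent(self) -> float:
        return self.frames.shape[1] * self.px_mm

    @property
    def lateral_half_width(self) -> float:
        return self.frames.shape[2] * self.px_mm / 2.0

    def _grid_origin(self) -> Tuple[float, float]:
        x0 = self.source_xy[0] - self.lateral_half_width
        y0 = self.source_xy[1] - self.downwind_extent
        return x0, y0

    def contains(self, x, y) -> np.ndarray:
        x0, y0 = self._grid_origin()
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= x0)
            & (x < x0 + self.frames.shape[2] * self.px_mm)
            & (y >= y0)
            & (y < y0 + self.frames.shape[1] * self.px_mm)
        )

    def at(self, x, y, t) -> np.ndarray:
        """Nearest-pixel, nearest-frame lookup; zero outside the domain.

        Frames loop in time, so trials may outlast the recording.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self._grid_origin()
        ix = np.floor((x - x0) / self.px_mm).astype(int)
        iy = np.floor((y - y0) / self.px_mm).astype(int)
        inside = (
            (ix >= 0)
            & (ix < self.frames.shape[2])
            & (iy >= 0)
            & (iy < self.frames.shape[1])
        )
        t = np.asarray(t, dtype=float)
        k = np.round(t * self.fps).astype(int) % self.frames.shape[0]
        out = np.zeros(np.broadcast(x, y, t).shape)
        if k.ndim == 0:
            frame = self.frames[int(k)]
            out[inside] = frame[iy[inside], ix[inside]]
        else:
            k, inside = np.broadcast_arrays(k, inside)
            ix, iy = np.broadcast_arrays(ix, iy)
            out[inside] = self.frames[k[inside], iy[inside], ix[inside]]
        return out

    # -- HDF5 round trip --------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset(
                "conc", data=self.frames.astype(np.float32), chunks=(1,) + self.frames.shape[1:]
            )
            d.attrs["px_mm"] = self.px_mm
            d.attrs["fps"] = self.fps
            d.attrs["source_xy"] = np.asarray(self.source_xy, dtype=float)

    @classmethod
    def from_hdf5(cls, path) -> "PlumeMovie":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["conc"]
            return cls(
                frames=d[...],
                px_mm=float(d.attrs["px_mm"]),
                fps=float(d.attrs["fps"]),
                source_xy=tuple(d.attrs["source_xy"]),
            )


@dataclass
class PlumeGenParams:
    """Parameters of the kinematic puff-plume generator.

    Defaults match the recorded plume's geometry (300 mm x +/-80 mm at
    0.74 mm/pixel, 15 Hz, 240 s) and the 10 cm/s tunnel flow.
    """

    mean_speed: float = 100.0  # mm/s downwind advection
    puff_rate: float = 8.0  # puffs released per second
    initial_width: float = 6.0  # mm Gaussian sigma at release
    spread_rate: float = 0.08  # mm of sigma per mm of travel
    meander_sigma: float = 8.0  # mm lateral SD of the centerline
    meander_tau: float = 2.0  # s centerline correlation time
    decay_length: float = 150.0  # mm amplitude e-folding distance
    px_mm: float = 0.74
    fps: float = 15.0
    duration: float = 240.0  # s
    downwind_extent: float = 300.0  # mm
    lateral_half_width: float = 80.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mean_speed", "puff_rate", "initial_width", "spread_rate",
            "meander_tau", "decay_length", "px_mm", "fps", "duration",
            "downwind_extent", "lateral_half_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.meander_sigma < 0:
            raise ValueError("meander_sigma must be non-negative")
        max_sigma = self.initial_width + self.spread_rate * self.downwind_extent
        if max_sigma + abs(self.meander_sigma) > 2 * self.lateral_half_width:
            raise ValueError("domain too small for the puff widths requested")


def make_synthetic_plume(p: PlumeGenParams, source_xy: Tuple[float, float] = (0.0, 300.0)) -> PlumeMovie:
    """Render a seeded puff-plume movie, normalized to the source pixel."""
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.fps
    n_frames = int(round(p.duration * p.fps))
    ny = int(round(p.downwind_extent / p.px_mm))
    nx = int(round(2 * p.lateral_half_width / p.px_mm))

    # centerline meander: stationary Ornstein-Uhlenbeck, SD meander_sigma
    m = np.zeros(n_frames)
    a = dt / p.meander_tau
    noise = rng.normal(0.0, 1.0, n_frames)
    for k in range(1, n_frames):
        m[k] = m[k - 1] * (1 - a) + p.meander_sigma * np.sqrt(2 * a) * noise[k]

    # puff release times (Poisson) and frozen lateral centers
    n_rel = rng.poisson(p.puff_rate * dt, n_frames)
    release_frames = np.repeat(np.arange(n_frames), n_rel)
    release_lat = m[release_frames]

    # lateral and downwind pixel-center axes, world frame
    x_axis = source_xy[0] - p.lateral_half_width + (np.arange(nx) + 0.5) * p.px_mm
    y_axis = source_xy[1] - p.downwind_extent + (np.arange(ny) + 0.5) * p.px_mm

    transit = p.downwind_extent / p.mean_speed  # s from source to far edge
    frames = np.zeros((n_frames, ny, nx), dtype=np.float64)

    order = np.argsort(release_frames)
    release_frames = release_frames[order]
    release_lat = release_lat[order]
    first_active = 0
    for k in range(n_frames):
        # drop puffs that have left the domain
        while (
            first_active < release_frames.size
            and (k - release_frames[first_active]) * dt > transit + 1.0
        ):
            first_active += 1
        active = slice(first_active, np.searchsorted(release_frames, k, side="right"))
        rf = release_frames[active]
        lat = release_lat[active]
        if rf.size == 0:
            continue
        d = (k - rf) * dt * p.mean_speed  # downwind distance of each puff
        sigma = p.initial_width + p.spread_rate * d
        # geometric dilution (2-D mass conservation) times an e-folding
        # absorption term, so the time-mean decays monotonically downwind
        amp = np.exp(-d / p.decay_length) * (p.initial_width / sigma) ** 2
        for dj, sj, aj, lj in zip(d, sigma, amp, lat):
            # local window of +/- 3 sigma around the puff center
            y_c = source_xy[1] - dj
            iy0 = np.searchsorted(y_axis, y_c - 3 * sj)
            iy1 = np.searchsorted(y_axis, y_c + 3 * sj)
            x_c = source_xy[0] + lj
            ix0 = np.searchsorted(x_axis, x_c - 3 * sj)
            ix1 = np.searchsorted(x_axis, x_c + 3 * sj)
            if iy0 >= iy1 or ix0 >= ix1:
                continue
            gy = np.exp(-((y_axis[iy0:iy1] - y_c) ** 2) / (2 * sj**2))
            gx = np.exp(-((x_axis[ix0:ix1] - x_c) ** 2) / (2 * sj**2))
            frames[k, iy0:iy1, ix0:ix1] += aj * np.outer(gy, gx)

    # normalize the time-mean at the source pixel to exactly 1
    ix_src = int(np.argmin(np.abs(x_axis - source_xy[0])))
    iy_src = ny - 1
    src_mean = frames[:, iy_src, ix_src].mean()
    if src_mean <= 0:
        raise ValueError("no odor reached the source pixel; check parameters")
    frames /= src_mean
    return PlumeMovie(frames.astype(np.float32), p.px_mm, p.fps, source_xy)


def intermittency_map(movie: PlumeMovie, threshold: float) -> np.ndarray:
    """Fraction of frames in which each pixel exceeds ``threshold``."""
    return (movie.frames > threshold).mean(axis=0)


# ---------------------------------------------------------------------------
# Environments (the navigation simulator's world interface)
# ---------------------------------------------------------------------------


@dataclass
class ArenaEnvironment:
    """Miniature wind-tunnel arena: a commanded waveform advecting downwind.

    The odor inlet sits at the upwind end (largest y); concentration is
    uniform across x and delayed by the advection time from the inlet.
    """

    stim_trace: SignalTrace
    adv: AdvectionModel = field(default_factory=AdvectionModel)
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((-20.0, 20.0), (0.0, 140.0))
    wind_upwind_deg: Optional[float] = 90.0

    @property
    def duration(self) -> float:
        return float(self.stim_trace.t[-1] + self.stim_trace.dt)

    def concentration(self, x, y, t) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        inlet_y = self.bounds[1][1]
        t_source = t - (inlet_y - y) / self.adv.wind_speed
        return np.interp(
            t_source, self.stim_trace.t, self.stim_trace.value, left=0.0, right=0.0
        )


def make_arena_env(
    stim: StimulusSpec,
    adv: Optional[AdvectionModel] = None,
    arena_bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((-20.0, 20.0), (0.0, 140.0)),
    sample_rate: float = 50.0,
) -> ArenaEnvironment:
    """Build an arena environment from a stimulus spec."""
    adv = AdvectionModel() if adv is None else adv
    return ArenaEnvironment(make_stimulus(stim, sample_rate), adv, arena_bounds)


@dataclass
class PlumeEnvironment:
    """A plume movie as a closed-loop world; wind blows from the source end."""

    movie: PlumeMovie
    duration: float = 180.0  # s per trial; the movie loops if shorter
    margin: float = 0.0  # mm of odor-free border around the movie domain
    wind_upwind_deg: Optional[float] = 90.0

    @property
    def bounds(self):
        x0 = self.movie.source_xy[0] - self.movie.lateral_half_width - self.margin
        x1 = self.movie.source_xy[0] + self.movie.lateral_half_width + self.margin
        y0 = self.movie.source_xy[1] - self.movie.downwind_extent - self.margin
        y1 = self.movie.source_xy[1]
        return ((x0, x1), (y0, y1))

    def concentration(self, x, y, t) -> np.ndarray:
        return self.movie.at(x, y, t)


@dataclass
class GradientEnvironment:
    """A static Gaussian odor gradient with no wind."""

    center_xy: Tuple[float, float] = (0.0, 150.0)
    spatial_sigma: float = 50.0  # mm
    peak: float = 1.0
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((-80.0, 80.0), (0.0, 300.0))
    duration: float = 180.0
    wind_upwind_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.peak <= 0:
            raise ValueError("peak must be positive")

    def concentration(self, x, y, t) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r2 = (x - self.center_xy[0]) ** 2 + (y - self.center_xy[1]) ** 2
        return self.peak * np.exp(-r2 / (2 * self.spatial_sigma**2))


# ---------------------------------------------------------------------------
# Synthetic behavioral data (stands in for real tracking tables)
# ---------------------------------------------------------------------------


def make_synthetic_behavior(
    stim: StimulusSpec,
    n_flies: int = 10,
    trials_per_fly: int = 3,
    nav_params=None,
    scale_sd_log: float = 0.0,
    noise_sd: float = 0.0,
    flip_rate: float = 0.0,
    seed: int = 0,
):
    """Simulate flies in the arena and emit raw-format trajectory tables.

    Returns ``(table, truth)``: a DataFrame in the raw tracking schema
    (t_s, x_mm, y_mm, orientation_deg, fly_id, trial_id, stimulus_id) and a
    dict of ground truth (navigation parameters, per-fly ON/OFF scales and
    injected flip segments).  ``scale_sd_log`` draws per-fly ON/OFF scales
    log-normally around 1; ``noise_sd`` (mm) adds tracking noise to the
    coordinates; ``flip_rate`` (events per second) injects spurious
    180-degree orientation flips.
    """
    import pandas as pd
    from dataclasses import replace as _replace

    from .simulate import NavParams, run_ensemble

    p = NavParams() if nav_params is None else nav_params
    rng = np.random.default_rng(seed)
    env = make_arena_env(stim)
    fs = 1.0 / p.dt

    if scale_sd_log > 0:
        scales = np.exp(rng.normal(0.0, scale_sd_log, (n_flies, 2)))
    else:
        scales = np.ones((n_flies, 2))

    rows = []
    flip_segments = []
    for fly in range(n_flies):
        pf = _replace(p, on_scale=scales[fly, 0], off_scale=scales[fly, 1])
        res = run_ensemble(
            env, pf, trials_per_fly, seed=int(rng.integers(2**31)), init_rule="uniform"
        )
        for trial in range(trials_per_fly):
            x = res.x[trial] + rng.normal(0.0, noise_sd, res.t.size)
            y = res.y[trial] + rng.normal(0.0, noise_sd, res.t.size)
            orientation = np.mod(res.heading[trial], 360.0)
            if flip_rate > 0:
                n_flips = rng.poisson(flip_rate * res.t[-1])
                pts = np.sort(rng.integers(1, res.t.size - 1, 2 * n_flips))
                for a, b in zip(pts[::2], pts[1::2]):
                    if b > a:
                        orientation[a:b] = np.mod(orientation[a:b] + 180.0, 360.0)
                        flip_segments.append((fly, trial, int(a), int(b)))
            rows.append(
                pd.DataFrame(
                    {
                        "t_s": res.t,
                        "x_mm": x,
                        "y_mm": y,
                        "orientation_deg": orientation,
                        "fly_id": fly,
                        "trial_id": trial,
                        "stimulus_id": stim.kind,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "nav_params": p,
        "per_fly_scales": scales,
        "flip_segments": flip_segments,
        "sample_rate": fs,
    }
    return table, truth
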