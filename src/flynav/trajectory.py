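"""Trajectory preprocessing, gait parameters, odor-time warping, and period statistics.

Raw tracking gives (x, y, orientation) at 50 Hz in a 14 x 4 cm arena with the
y axis increasing upwind.  The pipeline low-pass filters coordinates and
orientation (zero-phase 2-pole Butterworth at 2.5 Hz), repairs spurious 180
degree orientation flips, derives gait parameters with the standard moving /
turning thresholds (1 mm/s, 20 deg/mm), warps samples back by the advection
delay of the odor front, applies spatial exclusion rules, and runs the
paired before/during/after comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.stats import wilcoxon

from .signals import AdvectionModel, StimulusSpec

__all__ = [
    "Trajectory",
    "GaitSeries",
    "PeriodStats",
    "TrialRejected",
    "preprocess",
    "compute_gait",
    "warp_to_odor_time",
    "apply_exclusions",
    "period_compare",
    "empirical_d_function",
    "DEFAULT_ARENA",
]

DEFAULT_ARENA = (140.0, 40.0)  # mm, length (upwind) x width
MOVING_THRESHOLD = 1.0  # mm/s
TURN_THRESHOLD = 20.0  # deg/mm
MIN_PATH_LENGTH = 25.0  # mm per trial
FILTER_CUTOFF = 2.5  # Hz
WALL_MARGIN = 3.0  # mm


class TrialRejected(ValueError):
    """Raised when a trial fails an ingestion or exclusion rule."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class Trajectory:
    """A preprocessed walking trajectory in the arena frame (y increases upwind)."""

    t: np.ndarray  # s
    x: np.ndarray  # mm, lateral
    y: np.ndarray  # mm, upwind
    heading: np.ndarray  # deg, continuous (unwrapped)
    sample_rate: float = 50.0
    arena: Tuple[float, float] = DEFAULT_ARENA

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def path_length(self) -> float:
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


@dataclass
class GaitSeries:
    """Derived kinematic series with validity masks.

    Curvature and the turn indicator are defined only where the fly is
    moving; masked-out samples hold NaN.
    """

    t: np.ndarray
    ground_speed: np.ndarray  # mm/s
    upwind_velocity: np.ndarray  # mm/s
    angular_velocity: np.ndarray  # deg/s, absolute value
    curvature: np.ndarray  # deg/mm, NaN while stationary
    turn_indicator: np.ndarray  # 0/1, NaN while stationary
    moving_mask: np.ndarray  # bool
    valid_mask: np.ndarray  # bool; exclusion rules

    _FIELDS = (
        "ground_speed",
        "upwind_velocity",
        "angular_velocity",
        "curvature",
        "turn_indicator",
    )

    def masked(self, name: str) -> np.ndarray:
        """A series with invalid samples replaced by NaN."""
        v = getattr(self, name).astype(float).copy()
        v[~self.valid_mask] = np.nan
        return v


def _central_diff(v: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(v, dtype=float)
    d[1:-1] = (v[2:] - v[:-2]) / (2 * dt)
    d[0] = (v[1] - v[0]) / dt
    d[-1] = (v[-1] - v[-2]) / dt
    return d


def _wrap_deg(a):
    """Wrap angles to (-180, 180]."""
    return -np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) + 180.0


def _fix_orientation_flips(x, y, orientation, dt):
    """Repair sudden ~180 degree tracking flips in the orientation series.

    Per-sample orientation changes larger than 90 degrees are treated as
    tracking flips (a real fly cannot rotate that fast between 20-ms frames);
    each flip toggles a 180-degree offset.  The remaining global front/back
    ambiguity is resolved by choosing the branch that best matches the
    direction of movement over moving samples.
    """
    d = _wrap_deg(np.diff(orientation))
    flips = np.abs(d) > 90.0
    offset = np.concatenate([[0.0], np.cumsum(np.where(flips, 180.0, 0.0))])
    cont = np.unwrap(np.deg2rad(orientation))
    cont = np.rad2deg(cont) - offset
    # re-unwrap after offset removal to keep the series continuous
    cont = np.rad2deg(np.unwrap(np.deg2rad(cont)))

    vx, vy = np.diff(x) / dt, np.diff(y) / dt
    speed = np.hypot(vx, vy)
    moving = speed > MOVING_THRESHOLD
    if np.any(moving):
        travel = np.rad2deg(np.arctan2(vy[moving], vx[moving]))
        err0 = np.mean(np.abs(_wrap_deg(cont[:-1][moving] - travel)))
        err180 = np.mean(np.abs(_wrap_deg(cont[:-1][moving] + 180.0 - travel)))
        if err180 < err0:
            cont = cont + 180.0
    return cont


def preprocess(
    t,
    x,
    y,
    orientation,
    sample_rate: float = 50.0,
    arena: Tuple[float, float] = DEFAULT_ARENA,
) -> Trajectory:
    """Ingest a raw (t, x, y, orientation) table into a filtered Trajectory.

    Rejects trials with tracking gaps or with a total path length under
    25 mm; corrects 180-degree orientation flips; zero-phase low-pass
    filters coordinates and unwrapped orientation at 2.5 Hz (2-pole
    Butterworth).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    if t.size < 20:
        raise TrialRejected("too few samples")
    dt_nominal = 1.0 / sample_rate
    if np.any(np.abs(np.diff(t) - dt_nominal) > 0.25 * dt_nominal):
        raise TrialRejected("tracking gap: non-uniform sampling")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)) or np.any(~np.isfinite(orientation)):
        raise TrialRejected("tracking gap: missing samples")

    heading = _fix_orientation_flips(x, y, orientation, dt_nominal)

    b, a = butter(2, FILTER_CUTOFF / (sample_rate / 2.0))
    xf = filtfilt(b, a, x)
    yf = filtfilt(b, a, y)
    hf = filtfilt(b, a, heading)

    traj = Trajectory(t, xf, yf, hf, sample_rate, arena)
    if traj.path_length() < MIN_PATH_LENGTH:
        raise TrialRejected("moved less than 25 mm")
    return traj


def compute_gait(traj: Trajectory) -> GaitSeries:
    """Ground speed, upwind velocity, |angular velocity|, curvature and masks."""
    dt = traj.dt
    dx = _central_diff(traj.x, dt)
    dy = _central_diff(traj.y, dt)
    ground_speed = np.hypot(dx, dy)
    upwind_velocity = dy
    angular_velocity = np.abs(_central_diff(traj.heading, dt))
    moving = ground_speed >= MOVING_THRESHOLD

    curvature = np.full(len(traj), np.nan)
    curvature[moving] = angular_velocity[moving] / ground_speed[moving]
    turn = np.full(len(traj), np.nan)
    turn[moving] = (curvature[moving] > TURN_THRESHOLD).astype(float)

    return GaitSeries(
        t=traj.t,
        ground_speed=ground_speed,
        upwind_velocity=upwind_velocity,
        angular_velocity=angular_velocity,
        curvature=curvature,
        turn_indicator=turn,
        moving_mask=moving,
        valid_mask=np.ones(len(traj), dtype=bool),
    )


def warp_to_odor_time(
    gait: GaitSeries,
    traj: Trajectory,
    stim: StimulusSpec,
    adv: AdvectionModel,
) -> GaitSeries:
    """Shift each sample back by the advection delay to the fly's position.

    During the stimulus the delay is computed per frame from the fly's
    distance to the odor inlet (the upwind end of the arena); before and
    after the stimulus every sample is shifted by the delay at the fly's
    position at odor onset and offset respectively.  The mapping can skip or
    repeat samples but never reorders time.
    """
    fs = traj.sample_rate
    n = len(traj)
    inlet_y = traj.arena[0]
    delay = (inlet_y - traj.y) / adv.wind_speed  # s, per sample
    onset_i = int(round(stim.onset * fs))
    offset_i = int(round((stim.onset + stim.duration) * fs))
    onset_i = min(max(onset_i, 0), n - 1)
    offset_i = min(max(offset_i, 0), n - 1)

    shift = np.rint(delay * fs).astype(int)
    per_sample = shift.copy()
    per_sample[:onset_i] = shift[onset_i]
    per_sample[offset_i:] = shift[offset_i]
    target = np.arange(n) - per_sample
    # enforce monotonicity (the fly can outrun the mapping only transiently)
    target = np.maximum.accumulate(target)

    def _warp(v: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        ok = (target >= 0) & (target < n)
        out[target[ok]] = v[ok]  # later (in-order) writes repeat samples
        # fill skipped output slots from the nearest earlier sample
        idx = np.arange(n)
        have = ~np.isnan(out) if v.dtype.kind == "f" else np.ones(n, bool)
        if not np.all(have):
            last = np.maximum.accumulate(np.where(have, idx, -1))
            fillable = (last >= 0) & ~have
            out[fillable] = out[last[fillable]]
        return out

    warped = {name: _warp(getattr(gait, name).astype(float)) for name in GaitSeries._FIELDS}
    moving = _warp(gait.moving_mask.astype(float))
    valid = _warp(gait.valid_mask.astype(float))
    return GaitSeries(
        t=gait.t,
        moving_mask=moving >= 0.5,
        valid_mask=np.where(np.isnan(valid), False, valid >= 0.5),
        **warped,
    )


def apply_exclusions(
    gait: GaitSeries,
    traj: Trajectory,
    wall_margin: float = WALL_MARGIN,
    exclude_after_top: bool = True,
    top_margin: float = 1.0,
) -> GaitSeries:
    """Clear the validity mask near side walls and after reaching the top end."""
    valid = gait.valid_mask.copy()
    half_w = traj.arena[1] / 2.0
    near_wall = np.abs(traj.x) > (half_w - wall_margin)
    valid &= ~near_wall
    if exclude_after_top:
        at_top = traj.y >= traj.arena[0] - top_margin
        if np.any(at_top):
            valid[np.argmax(at_top):] = False
    return GaitSeries(
        t=gait.t,
        ground_speed=gait.ground_speed,
        upwind_velocity=gait.upwind_velocity,
        angular_velocity=gait.angular_velocity,
        curvature=gait.curvature,
        turn_indicator=gait.turn_indicator,
        moving_mask=gait.moving_mask,
        valid_mask=valid,
    )


DEFAULT_WINDOWS = {
    "before": (-30.0, 0.0),  # relative to odor onset
    "during": (2.0, 3.0),  # relative to odor onset
    "after": (11.0, 13.0),  # relative to onset, i.e. 1-3 s after a 10-s pulse
}


@dataclass
class PeriodStats:
    """Paired before/during/after comparisons across flies."""

    windows: Dict[str, Tuple[float, float]]
    per_fly_means: np.ndarray  # (n_flies, 3): before, during, after
    p_values: Dict[str, float]
    alpha_corrected: float
    significant: Dict[str, bool] = field(default_factory=dict)


def signed_rank_test(x, y, exact_threshold: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank paired test.

    Zeros are dropped and ties mid-ranked; the exact null distribution is
    used up to ``exact_threshold`` non-zero pairs, the normal approximation
    with continuity correction beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= exact_threshold else "approx"
    kwargs = {"correction": True} if method == "approx" else {}
    return float(wilcoxon(d, method=method, **kwargs).pvalue)


def period_compare(
    t: np.ndarray,
    per_fly_series: Sequence[np.ndarray],
    per_fly_moving: Optional[Sequence[np.ndarray]] = None,
    onset: float = 0.0,
    windows: Optional[Dict[str, Tuple[float, float]]] = None,
    alpha: float = 0.05,
) -> PeriodStats:
    """Per-fly window means and paired signed-rank tests with Bonferroni control.

    Window bounds are in seconds relative to odor onset; means include
    moving samples only when ``per_fly_moving`` masks are given.
    """
    if len(per_fly_series) < 5:
        raise ValueError("need at least 5 flies for the paired comparisons")
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)
    names = list(windows)

    t = np.asarray(t, dtype=float)
    means = np.empty((len(per_fly_series), len(names)))
    for i, series in enumerate(per_fly_series):
        series = np.asarray(series, dtype=float)
        mask = np.ones(series.size, dtype=bool)
        if per_fly_moving is not None:
            mask = np.asarray(per_fly_moving[i], dtype=bool)
        for j, name in enumerate(names):
            lo, hi = windows[name]
            sel = (t >= onset + lo) & (t < onset + hi) & mask & np.isfinite(series)
            if not np.any(sel):
                raise ValueError(f"empty window {name!r} for fly {i}")
            means[i, j] = np.mean(series[sel])

    pairs = [(0, 1), (0, 2), (1, 2)]
    alpha_corr = alpha / len(pairs)
    p_values, significant = {}, {}
    for a, b in pairs:
        key = f"{names[a]}-{names[b]}"
        p = signed_rank_test(means[:, a], means[:, b])
        p_values[key] = p
        significant[key] = p < alpha_corr
    return PeriodStats(windows, means, p_values, alpha_corr, significant)


def empirical_d_function(
    traj: Trajectory,
    wind_upwind_deg: float = 90.0,
    n_bins: int = 18,
    moving_mask: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean signed angular velocity as a function of wind angle psi.

    ``psi`` is the signed angle from the fly's heading to the upwind
    direction, wrapped to (-180, 180], binned circularly (default 18 bins of
    20 degrees).  Returns (bin centers in deg, mean deg/s per bin; NaN for
    unvisited bins).
    """
    dt = traj.dt
    dh = _central_diff(traj.heading, dt)  # signed, deg/s
    psi = _wrap_deg(wind_upwind_deg - traj.heading)
    sel = np.ones(len(traj), dtype=bool)
    if moving_mask is not None:
        sel &= np.asarray(moving_mask, dtype=bool)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(psi[sel], edges) - 1, 0, n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = which == b
        if np.any(m):
            out[b] = np.mean(dh[sel][m])
    return centers, out
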