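"""Success metrics, proportion statistics, spatial maps and scale sweeps.

Success in a plume (or gradient) trial means the agent came within a fixed
radius (default 20 mm) of the odor source at any time during the trial,
boundary inclusive.  Proportions carry the binomial standard error
sqrt(p (1 - p) / n); pairs of proportions are compared with a pooled
two-proportion z test and a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .simulate import EnsembleResult, NavParams, run_ensemble

__all__ = [
    "ProportionStats",
    "success_rate",
    "compare_proportions",
    "spatial_on_off_maps",
    "occupancy_map",
    "SweepGrid",
    "sweep_scales",
]

SUCCESS_RADIUS = 20.0  # mm


@dataclass
class ProportionStats:
    """A success proportion with its binomial standard error."""

    successes: int
    n: int
    label: str = ""

    @property
    def p(self) -> float:
        return self.successes / self.n

    @property
    def se(self) -> float:
        return float(np.sqrt(self.p * (1.0 - self.p) / self.n))


def _trial_successes(result: EnsembleResult, source_xy, radius: float) -> np.ndarray:
    d2 = (result.x - source_xy[0]) ** 2 + (result.y - source_xy[1]) ** 2
    return (d2 <= radius**2).any(axis=1)


def success_rate(
    result: EnsembleResult,
    source_xy: Tuple[float, float],
    radius: float = SUCCESS_RADIUS,
    label: str = "",
) -> ProportionStats:
    """Proportion of trials that ever came within ``radius`` of the source."""
    if result is None or result.n_trials == 0:
        raise ValueError("no trials")
    hits = _trial_successes(result, source_xy, radius)
    return ProportionStats(int(hits.sum()), result.n_trials, label)


def compare_proportions(a: ProportionStats, b: ProportionStats) -> Tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value."""
    if a.n == 0 or b.n == 0:
        raise ValueError("empty sample")
    pooled = (a.successes + b.successes) / (a.n + b.n)
    denom = np.sqrt(pooled * (1.0 - pooled) * (1.0 / a.n + 1.0 / b.n))
    if denom == 0:
        return 0.0, 1.0
    z = (a.p - b.p) / denom
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def _bin_edges(bounds, grid_shape):
    (x0, x1), (y0, y1) = bounds
    return (
        np.linspace(x0, x1, grid_shape[1] + 1),
        np.linspace(y0, y1, grid_shape[0] + 1),
    )


def spatial_on_off_maps(
    result: EnsembleResult,
    bounds,
    grid_shape: Tuple[int, int] = (30, 16),
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean ON and OFF response per spatial bin over all trials and samples.

    Returns two (ny, nx) arrays; bins never visited hold NaN.
    """
    xe, ye = _bin_edges(bounds, grid_shape)
    x = result.x.ravel()
    y = result.y.ravel()
    count, _, _ = np.histogram2d(y, x, bins=(ye, xe))
    on_sum, _, _ = np.histogram2d(y, x, bins=(ye, xe), weights=result.on.ravel())
    off_sum, _, _ = np.histogram2d(y, x, bins=(ye, xe), weights=result.off.ravel())
    with np.errstate(invalid="ignore"):
        on_map = np.where(count > 0, on_sum / np.maximum(count, 1), np.nan)
        off_map = np.where(count > 0, off_sum / np.maximum(count, 1), np.nan)
    return on_map, off_map


def occupancy_map(
    result: EnsembleResult,
    bounds,
    grid_shape: Tuple[int, int] = (30, 16),
    log_scale: bool = False,
) -> np.ndarray:
    """Proportion of total time spent in each spatial bin (sums to 1).

    With ``log_scale`` the log10 of the proportion is returned, floored at
    the proportion corresponding to a single sample to avoid -inf.
    """
    xe, ye = _bin_edges(bounds, grid_shape)
    count, _, _ = np.histogram2d(result.y.ravel(), result.x.ravel(), bins=(ye, xe))
    total = count.sum()
    prop = count / total
    if not log_scale:
        return prop
    floor = 1.0 / total
    return np.log10(np.maximum(prop, floor))


@dataclass
class SweepGrid:
    """Success rates over a 2-D grid of model-parameter scalings."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    success: np.ndarray  # (len(axis1), len(axis2)) proportions
    n_per_cell: int


_AXES = {
    "on_scale": lambda p, v: replace(p, on_scale=v),
    "off_scale": lambda p, v: replace(p, off_scale=v),
    "wind": lambda p, v: replace(p, kappa5=p.kappa5 * v, kappa6=p.kappa6 * v),
    "kappa7": lambda p, v: replace(p, kappa7=v),
}


def sweep_scales(
    env,
    base: NavParams,
    axis1: Tuple[str, Sequence[float]],
    axis2: Tuple[str, Sequence[float]],
    n_per_cell: int = 100,
    seed: int = 0,
    source_xy: Optional[Tuple[float, float]] = None,
    radius: float = SUCCESS_RADIUS,
    duration: Optional[float] = None,
) -> SweepGrid:
    """Seeded success-rate grid over two parameter axes.

    Axis names: ``on_scale``, ``off_scale``, ``wind`` (a common multiplier
    on both wind-steering coefficients), ``kappa7`` (bilateral gain).  Each
    cell runs an independent ensemble seeded reproducibly from
    (seed, cell index).
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    for name in (name1, name2):
        if name not in _AXES:
            raise ValueError(f"unknown sweep axis {name!r}")
    if source_xy is None:
        source_xy = env.movie.source_xy
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    success = np.empty((vals1.size, vals2.size))
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(vals1.size * vals2.size) % (2**31)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            p = _AXES[name2](_AXES[name1](base, v1), v2)
            res = run_ensemble(
                env, p, n_per_cell,
                seed=int(cell_seeds[i * vals2.size + j]),
                duration=duration,
            )
            success[i, j] = success_rate(res, source_xy, radius).p
    return SweepGrid(name1, vals1, name2, vals2, success, n_per_cell)
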