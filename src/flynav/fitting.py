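"""Nonlinear least-squares fitting of response models and dose-response curves.

The behavioral prediction for a stimulus is ``baseline + scale * model(stim)``
where ``model`` is an :class:`~flynav.response.OdorResponseModel`; all free
parameters (time constants, output gain, optionally the baseline) are fitted
jointly across every stimulus/target pair by pooled sum-of-squares, with
multi-start to guard against local minima.  The baseline Hill constant kd is
held fixed during response-model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema
from sklearn.base import BaseEstimator, RegressorMixin

from .response import KD_BASELINE, OdorResponseModel
from .signals import SignalTrace

__all__ = [
    "rmse",
    "pearson",
    "predict_behavior",
    "ResponseModelRegressor",
    "HillRegressor",
    "CycleModulationResult",
    "jackknife_cycle_modulation",
]


def rmse(prediction, target) -> float:
    """Root mean squared error between two aligned series."""
    p = np.asarray(prediction, dtype=float)
    t = np.asarray(target, dtype=float)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def pearson(prediction, target) -> float:
    """Pearson linear correlation coefficient between two aligned series."""
    p = np.asarray(prediction, dtype=float)
    t = np.asarray(target, dtype=float)
    return float(np.corrcoef(p, t)[0, 1])


def predict_behavior(model_output: SignalTrace, scale: float, baseline: float = 0.0) -> SignalTrace:
    """Behavioral prediction = baseline + scale * model output."""
    return model_output.copy_with(baseline + scale * model_output.value)


class ResponseModelRegressor(BaseEstimator, RegressorMixin):
    """Joint multi-stimulus fit of one ON/OFF response-model variant.

    Parameters
    ----------
    variant, channel : str
        Model structure; see :class:`~flynav.response.OdorResponseModel`.
    kd : float
        Baseline Hill constant, held fixed (not co-fitted).
    init : dict or None
        Initial guesses for the free parameters.  Keys among ``tau_on``,
        ``tau_a``, ``tau_off1``, ``tau_off2``, ``scale``; missing keys fall
        back to the published best-fit values for the variant.
    fit_baseline : bool
        If False (default) the prediction baseline for each target is fixed
        to the mean of its pre-odor segment (``baseline_window`` seconds);
        if True a single shared baseline is co-fitted.
    n_starts : int
        Number of optimizer starts; starts beyond the first perturb the
        initial guesses log-uniformly within a factor ``start_spread``.
    seed : int
        Seed for the multi-start perturbations.

    Attributes
    ----------
    tau_on_, tau_a_, tau_off1_, tau_off2_, scale_, baseline_ : float
        Fitted parameters (those relevant to the variant/channel).
    rmse_, pearson_r_ : float
        Fit quality over the pooled (concatenated) traces.
    converged_ : bool
    start_points_ : list of dict
    """

    def __init__(
        self,
        variant: str = "ACF",
        channel: str = "ON",
        kd: float = KD_BASELINE,
        init: Optional[dict] = None,
        fit_baseline: bool = False,
        baseline_window: float = 5.0,
        n_starts: int = 10,
        start_spread: float = 4.0,
        seed: int = 0,
    ):
        self.variant = variant
        self.channel = channel
        self.kd = kd
        self.init = init
        self.fit_baseline = fit_baseline
        self.baseline_window = baseline_window
        self.n_starts = n_starts
        self.start_spread = start_spread
        self.seed = seed

    # -- parameter vector <-> named parameters ---------------------------
    def _free_names(self) -> List[str]:
        adapt = self.variant in ("ACF", "FAC")
        if self.channel == "ON":
            names = ["tau_on"]
        else:
            names = ["tau_off1", "tau_off2"]
        if adapt:
            names.append("tau_a")
        names.append("scale")
        return names

    def _default_init(self) -> dict:
        from .response import TABLE_OFF, TABLE_ON

        table = TABLE_ON if self.channel == "ON" else TABLE_OFF
        row = dict(table.get(self.variant, table["ACF"]))
        init = {k: row[k] for k in self._free_names() if k in row and row[k] is not None}
        init.setdefault("tau_a", 10.0)
        init.setdefault("scale", row.get("scale", 1.0))
        return init

    def _pack(self, named: dict) -> np.ndarray:
        # log-parameterization keeps time constants and scale positive; the
        # OFF slow constant is parameterized as a positive offset above the
        # fast one so the ordering constraint holds throughout optimization
        x = []
        for name in self._free_names():
            if name == "tau_off2":
                x.append(np.log(named["tau_off2"] - named["tau_off1"]))
            else:
                x.append(np.log(named[name]))
        if self.fit_baseline:
            x.append(named.get("baseline", 0.0))
        return np.array(x)

    def _unpack(self, x: np.ndarray) -> dict:
        named = {}
        for name, xi in zip(self._free_names(), x):
            named[name] = np.exp(xi)
        if "tau_off2" in named:
            named["tau_off2"] = named["tau_off1"] + named["tau_off2"]
        if self.fit_baseline:
            named["baseline"] = x[-1]
        return named

    def _model(self, named: dict) -> OdorResponseModel:
        return OdorResponseModel(
            variant=self.variant,
            channel=self.channel,
            kd=self.kd,
            tau_a=named.get("tau_a"),
            tau_on=named.get("tau_on", 1.0),
            tau_off1=named.get("tau_off1", 0.5),
            tau_off2=named.get("tau_off2", 5.0),
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, stimuli: Sequence[SignalTrace], targets: Sequence[SignalTrace]):
        if len(stimuli) == 0 or len(stimuli) != len(targets):
            raise ValueError("need equal, non-empty stimulus and target lists")
        for s, y in zip(stimuli, targets):
            if len(s) != len(y):
                raise ValueError("each stimulus/target pair must share a grid")

        if self.fit_baseline:
            baselines = None
        else:
            baselines = []
            for s, y in zip(stimuli, targets):
                n0 = max(1, int(round(self.baseline_window * s.sample_rate)))
                baselines.append(float(np.mean(y.value[:n0])))

        y_all = np.concatenate([y.value for y in targets])

        def residuals(x: np.ndarray) -> np.ndarray:
            named = self._unpack(x)
            model = self._model(named)
            preds = []
            for i, s in enumerate(stimuli):
                out = model.transform(s).value
                b = named["baseline"] if self.fit_baseline else baselines[i]
                preds.append(b + named["scale"] * out)
            return np.concatenate(preds) - y_all

        init = self._default_init()
        if self.init:
            init.update(self.init)
        rng = np.random.default_rng(self.seed)

        starts = [dict(init)]
        for _ in range(self.n_starts - 1):
            pert = dict(init)
            for name in self._free_names():
                f = self.start_spread ** rng.uniform(-1.0, 1.0)
                pert[name] = init[name] * f
            if "tau_off2" in pert and pert["tau_off2"] <= pert["tau_off1"]:
                pert["tau_off1"], pert["tau_off2"] = (
                    pert["tau_off2"] * 0.5,
                    pert["tau_off1"] * 2.0,
                )
            starts.append(pert)

        best = None
        self.start_points_ = starts
        for start in starts:
            res = least_squares(
                residuals,
                self._pack(start),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
            if best is None or res.cost < best.cost:
                best = res

        named = self._unpack(best.x)
        for name, value in named.items():
            setattr(self, name + "_", float(value))
        if not self.fit_baseline:
            self.baseline_ = baselines
        pred_all = residuals(best.x) + y_all
        self.rmse_ = rmse(pred_all, y_all)
        self.pearson_r_ = pearson(pred_all, y_all)
        self.n_points_ = y_all.size
        self.converged_ = bool(best.success)
        return self

    def predict(self, stimuli: Sequence[SignalTrace]) -> List[SignalTrace]:
        named = {n: getattr(self, n + "_") for n in self._free_names()}
        model = self._model(named)
        b = self.baseline_ if np.isscalar(self.baseline_) else 0.0
        return [predict_behavior(model.run(s).output, self.scale_, b) for s in stimuli]


class HillRegressor(BaseEstimator, RegressorMixin):
    """Least-squares Hill dose-response fit R(c) = baseline + rmax c^n / (c^n + kd^n).

    Attributes after fitting: ``kd_`` (same units as the concentrations,
    typically % ACV), ``hill_n_``, ``rmax_``, ``baseline_``, ``rmse_``,
    ``converged_``.
    """

    def __init__(
        self,
        init: Optional[dict] = None,
        fit_baseline: bool = False,
        n_starts: int = 10,
        start_spread: float = 4.0,
        seed: int = 0,
    ):
        self.init = init
        self.fit_baseline = fit_baseline
        self.n_starts = n_starts
        self.start_spread = start_spread
        self.seed = seed

    def fit(self, concentrations, responses):
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(responses, dtype=float)
        n_free = 4 if self.fit_baseline else 3
        if c.size < max(4, n_free + 1):
            raise ValueError("need at least 4 dose-response points")
        if np.ptp(y) == 0:
            raise ValueError("flat responses: Hill parameters unidentifiable")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")

        init = dict(kd=np.exp(np.mean(np.log(c))), hill_n=1.0, rmax=float(np.max(y)))
        if self.init:
            init.update(self.init)

        def residuals(x):
            kd, n, rmax = np.exp(x[:3])
            b = x[3] if self.fit_baseline else 0.0
            return b + rmax * c**n / (c**n + kd**n) - y

        rng = np.random.default_rng(self.seed)
        starts = [init]
        for _ in range(self.n_starts - 1):
            starts.append(
                {
                    k: init[k] * self.start_spread ** rng.uniform(-1, 1)
                    for k in ("kd", "hill_n", "rmax")
                }
            )

        best = None
        for s in starts:
            x0 = [np.log(s["kd"]), np.log(s["hill_n"]), np.log(max(s["rmax"], 1e-12))]
            if self.fit_baseline:
                x0.append(float(np.min(y)))
            res = least_squares(
                residuals, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            if best is None or res.cost < best.cost:
                best = res

        self.kd_, self.hill_n_, self.rmax_ = (float(v) for v in np.exp(best.x[:3]))
        self.baseline_ = float(best.x[3]) if self.fit_baseline else 0.0
        self.rmse_ = rmse(residuals(best.x) + y, y)
        self.converged_ = bool(best.success)
        return self

    def predict(self, concentrations):
        c = np.asarray(concentrations, dtype=float)
        n = self.hill_n_
        return self.baseline_ + self.rmax_ * c**n / (c**n + self.kd_**n)


@dataclass
class CycleModulationResult:
    """Per-cycle modulation amplitudes with jackknife standard errors."""

    cycle_freqs: np.ndarray  # Hz, one per stimulus cycle
    amplitude: np.ndarray  # mean min-to-max modulation per cycle
    se: np.ndarray  # jackknife SE per cycle
    cycle_bounds: np.ndarray = field(default=None, repr=False)  # sample indices


def _cycle_boundaries(stim: SignalTrace, boundaries: str, smooth_s: float) -> np.ndarray:
    v = gaussian_filter1d(stim.value, smooth_s * stim.sample_rate)
    order = max(1, int(0.1 * stim.sample_rate))
    if boundaries == "minima":
        idx = argrelextrema(v, np.less_equal, order=order)[0]
    elif boundaries == "maxima":
        idx = argrelextrema(v, np.greater_equal, order=order)[0]
    else:
        raise ValueError("boundaries must be 'minima' or 'maxima'")
    # collapse flat runs of equal extrema to single boundaries
    if idx.size:
        keep = np.concatenate([[True], np.diff(idx) > order])
        idx = idx[keep]
    # only boundaries where the stimulus is actually modulated
    active = np.flatnonzero(stim.value > 1e-12)
    if active.size == 0:
        return np.array([], dtype=int)
    idx = idx[(idx >= active[0] - order) & (idx <= active[-1] + order)]
    return idx


def jackknife_cycle_modulation(
    per_fly_traces: Sequence[np.ndarray],
    stimulus: SignalTrace,
    n_drop: int = 1,
    boundaries: str = "minima",
    smooth_s: float = 0.5,
) -> CycleModulationResult:
    """Per-cycle response modulation with leave-out jackknife errors.

    Cycle limits are the local minima (ascending sweeps) or maxima
    (descending sweeps) of the smoothed stimulus.  For each cycle, the
    min-to-max amplitude of every leave-``n_drop``-out mean trace is
    computed; the reported amplitude is the mean across estimates and the SE
    is the jackknife formula sqrt((n-1)/n * sum_i (a_i - a)^2) with ``a``
    the amplitude of the all-traces mean and ``n`` the number of estimates.
    """
    traces = [np.asarray(x, dtype=float) for x in per_fly_traces]
    if len(traces) < 2:
        raise ValueError("need at least two traces for a jackknife")
    X = np.stack(traces)
    bounds = _cycle_boundaries(stimulus, boundaries, smooth_s)
    if bounds.size < 2:
        raise ValueError("no detectable stimulus cycles")

    n_groups = int(np.ceil(len(traces) / n_drop))
    grand = X.mean(axis=0)

    freqs, amps, ses = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = slice(a, b + 1)
        estimates = []
        for g in range(n_groups):
            mask = np.ones(len(traces), dtype=bool)
            mask[g * n_drop : (g + 1) * n_drop] = False
            m = X[mask].mean(axis=0)[seg]
            estimates.append(np.max(m) - np.min(m))
        estimates = np.asarray(estimates)
        full = np.max(grand[seg]) - np.min(grand[seg])
        n = len(estimates)
        se = np.sqrt((n - 1) / n * np.sum((estimates - full) ** 2))
        freqs.append(stimulus.sample_rate / (b - a))
        amps.append(estimates.mean())
        ses.append(se)

    return CycleModulationResult(
        np.asarray(freqs), np.asarray(amps), np.asarray(ses), bounds
    )
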