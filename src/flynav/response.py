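"""Phenomenological ON and OFF odor-response models.

The ON response (upwind run) is modeled as adaptive compression of the odor
waveform followed by first-order low-pass filtering; the OFF response (offset
search) replaces the low-pass with a rectified fast-minus-slow differential
filter.  Four variants are supported:

    ACF  adaptive compression, then filtering      (the models of choice)
    FAC  filtering, then adaptive compression
    CF   static compression, then filtering        (no adaptation)
    FC   filtering, then static compression        (no adaptation)

Adaptive compression is a Hill function with exponent 1 whose half-maximum
point is pushed rightward by a slowly integrated odor history A(t):

    tau_A dA/dt = odor - A
    C = odor / (odor + kd + A)

All differential equations are integrated with the forward Euler method at a
20 ms time step, matching the behavioral sampling; the update for each
first-order stage is y[n] = y[n-1] + (dt/tau) * (x[n-1] - y[n-1]) from a zero
initial state (trials begin after a long odor-free period, so zero is the
resting state of every filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter
from sklearn.base import BaseEstimator

from .signals import SignalTrace

__all__ = [
    "MODEL_VARIANTS",
    "TABLE_ON",
    "TABLE_OFF",
    "adaptive_compress",
    "static_compress",
    "lowpass",
    "off_filter",
    "OdorResponseModel",
    "ModelStateTrace",
]

MODEL_VARIANTS = ("ACF", "FAC", "CF", "FC")

# Published best-fit parameters of the four ON models
# (tau_on, tau_a, scale); adaptation-free variants carry tau_a=None.
TABLE_ON = {
    "FAC": dict(tau_on=0.34, tau_a=20.36, scale=5.9),
    "ACF": dict(tau_on=0.72, tau_a=9.8, scale=7.3),
    "FC": dict(tau_on=0.04, tau_a=None, scale=4.4),
    "CF": dict(tau_on=0.3, tau_a=None, scale=4.5),
}

# Published best-fit parameters of the four OFF models
# (tau_off1 fast, tau_off2 slow, tau_a, scale).
TABLE_OFF = {
    "FAC": dict(tau_off1=0.76, tau_off2=3.96, tau_a=16.7, scale=0.3),
    "ACF": dict(tau_off1=0.62, tau_off2=4.84, tau_a=10.08, scale=0.6),
    "FC": dict(tau_off1=0.58, tau_off2=3.0, tau_a=None, scale=0.1),
    "CF": dict(tau_off1=0.06, tau_off2=5.02, tau_a=None, scale=0.3),
}

KD_BASELINE = 0.01  # normalized concentration; from square-pulse dose fits


def _euler_lowpass(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Forward-Euler first-order low-pass from zero initial state.

    Equivalent to the loop ``y[n] = y[n-1] + (dt/tau)*(x[n-1] - y[n-1])``.
    """
    if tau <= 0:
        raise ValueError("time constant must be positive")
    a = dt / tau
    # y[n] - (1-a) y[n-1] = a x[n-1]
    return lfilter([0.0, a], [1.0, -(1.0 - a)], np.asarray(x, dtype=float))


def lowpass(x: SignalTrace, tau: float, dt: Optional[float] = None) -> SignalTrace:
    """First-order Euler low-pass of a trace (zero initial state)."""
    dt = x.dt if dt is None else dt
    return x.copy_with(_euler_lowpass(x.value, tau, dt))


def adaptive_compress(stim: SignalTrace, kd: float, tau_a: float, dt: Optional[float] = None):
    """Adaptation state A(t) and compressed signal C(t) for an odor trace.

    Returns ``(A, C)`` traces.  A is a slow Euler low-pass of the odor; C is
    the Hill compression with half-max at ``kd + A``.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    dt = stim.dt if dt is None else dt
    odor = stim.value
    A = _euler_lowpass(odor, tau_a, dt)
    C = odor / (odor + kd + A)
    return stim.copy_with(A), stim.copy_with(C)


def static_compress(stim: SignalTrace, kd: float) -> SignalTrace:
    """Memoryless Hill compression with exponent 1 (no adaptation)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    odor = stim.value
    return stim.copy_with(odor / (odor + kd))


def off_filter(C: SignalTrace, tau_fast: float, tau_slow: float, dt: Optional[float] = None):
    """Rectified differential filter: OFF = max(0, slow - fast).

    Returns ``(R1, R2, OFF)`` traces, where R1/R2 are the fast/slow
    first-order low-passes of the input.
    """
    if not tau_fast < tau_slow:
        raise ValueError("tau_fast must be smaller than tau_slow")
    dt = C.dt if dt is None else dt
    r1 = _euler_lowpass(C.value, tau_fast, dt)
    r2 = _euler_lowpass(C.value, tau_slow, dt)
    off = np.maximum(0.0, r2 - r1)
    return C.copy_with(r1), C.copy_with(r2), C.copy_with(off)


@dataclass
class ModelStateTrace:
    """All internal state traces of one model run.

    ``output`` is the unscaled ON(t) or OFF(t); multiplying by the fitted
    output gain (and adding a behavioral baseline) is the business of the
    prediction step in :mod:`flynav.fitting`.
    """

    odor: SignalTrace
    A: Optional[SignalTrace]
    C: SignalTrace
    R1: Optional[SignalTrace]
    R2: Optional[SignalTrace]
    output: SignalTrace

    def to_frame(self):
        """Multi-column DataFrame (t, odor, A, C, R1, R2, output)."""
        import pandas as pd

        cols = {"t": self.odor.t, "odor": self.odor.value, "C": self.C.value}
        if self.A is not None:
            cols["A"] = self.A.value
        if self.R1 is not None:
            cols["R1"] = self.R1.value
            cols["R2"] = self.R2.value
        cols["output"] = self.output.value
        return pd.DataFrame(cols)


class OdorResponseModel(BaseEstimator):
    """Stateless transformer from an odor trace to an ON or OFF trace.

    Parameters
    ----------
    variant : {"ACF", "FAC", "CF", "FC"}
        Order of compression and filtering, with ("A") or without adaptation.
    channel : {"ON", "OFF"}
        Low-pass (ON) or rectified differential (OFF) filtering stage.
    kd : float
        Baseline Hill half-max concentration (normalized), default 0.01.
    tau_a : float or None
        Adaptation time constant (s); required for ACF/FAC.
    tau_on : float
        ON low-pass time constant (s).
    tau_off1, tau_off2 : float
        Fast and slow OFF filter time constants (s), ``tau_off1 < tau_off2``.
    dt : float or None
        Euler step (s); defaults to the input trace's own sample interval.
    """

    def __init__(
        self,
        variant: str = "ACF",
        channel: str = "ON",
        kd: float = KD_BASELINE,
        tau_a: Optional[float] = 9.8,
        tau_on: float = 0.72,
        tau_off1: float = 0.62,
        tau_off2: float = 4.84,
        dt: Optional[float] = None,
    ):
        self.variant = variant
        self.channel = channel
        self.kd = kd
        self.tau_a = tau_a
        self.tau_on = tau_on
        self.tau_off1 = tau_off1
        self.tau_off2 = tau_off2
        self.dt = dt

    @classmethod
    def from_table(cls, variant: str, channel: str, dt: Optional[float] = None):
        """Model pre-loaded with the published best-fit parameters."""
        if channel == "ON":
            row = TABLE_ON[variant]
            return cls(variant, "ON", tau_on=row["tau_on"], tau_a=row["tau_a"], dt=dt)
        row = TABLE_OFF[variant]
        return cls(
            variant,
            "OFF",
            tau_off1=row["tau_off1"],
            tau_off2=row["tau_off2"],
            tau_a=row["tau_a"],
            dt=dt,
        )

    def _validate(self) -> None:
        if self.variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.channel not in ("ON", "OFF"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.variant in ("ACF", "FAC") and self.tau_a is None:
            raise ValueError(f"variant {self.variant} requires tau_a")
        if self.channel == "OFF" and not self.tau_off1 < self.tau_off2:
            raise ValueError("OFF channel requires tau_off1 < tau_off2")

    def transform(self, stim: SignalTrace) -> SignalTrace:
        """Unscaled ON(t) or OFF(t) response to an odor trace."""
        return self.run(stim).output

    def run(self, stim: SignalTrace) -> ModelStateTrace:
        """Full state traces (A, C, R1, R2, output) of one model run."""
        self._validate()
        dt = stim.dt if self.dt is None else self.dt
        adapt = self.variant in ("ACF", "FAC")
        compress_first = self.variant in ("ACF", "CF")

        A = None
        if compress_first:
            if adapt:
                A, C = adaptive_compress(stim, self.kd, self.tau_a, dt)
            else:
                C = static_compress(stim, self.kd)
            if self.channel == "ON":
                out = lowpass(C, self.tau_on, dt)
                return ModelStateTrace(stim, A, C, None, None, out)
            r1, r2, out = off_filter(C, self.tau_off1, self.tau_off2, dt)
            return ModelStateTrace(stim, A, C, r1, r2, out)

        # filter-first orders: the raw odor is filtered, then compressed;
        # in FAC the adaptation state is still driven by the raw odor.
        if self.channel == "ON":
            filtered = lowpass(stim, self.tau_on, dt)
            r1 = r2 = None
        else:
            r1, r2, filtered = off_filter(stim, self.tau_off1, self.tau_off2, dt)
        f = filtered.value
        if adapt:
            A = stim.copy_with(_euler_lowpass(stim.value, self.tau_a, dt))
            C = stim.copy_with(f / (f + self.kd + A.value))
        else:
            C = stim.copy_with(f / (f + self.kd))
        return ModelStateTrace(stim, A, C, r1, r2, C)
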