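"""Photoacoustic quantification of nanocarrier degradation.

The peak-to-peak photoacoustic amplitude of a nanoparticle suspension is
proportional to the concentration of intact particles, so its decay after a
degradation trigger (e.g. transfer into phosphate buffer) reads out the
degradation kinetics.  The summary statistic is the degradation time
``t85``: the time at which the amplitude has fallen by 85% of its total
max-to-min excursion, located by linear interpolation between the bracketing
samples after the trace maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PATrace",
    "FlatTraceError",
    "ThresholdNotReachedError",
    "degradation_time",
    "amplitude_to_concentration",
    "DECREASE_FRACTION",
]

#: Fractional amplitude decrease (from max towards min) defining t85.
DECREASE_FRACTION = 0.85


class FlatTraceError(ValueError):
    """The trace has no amplitude excursion; the statistic is undefined."""


class ThresholdNotReachedError(ValueError):
    """The trace never decays through the 85%-decrease threshold."""


@dataclass(frozen=True)
class PATrace:
    """A photoacoustic amplitude record: times (s) and peak-to-peak
    amplitudes (arbitrary units)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and amplitudes must be 1-D and equal "
                             "length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("times and amplitudes must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    if window < 2:
        return a
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(a, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + a.size]
    return out


def degradation_time(trace: PATrace, smooth_window: int | None = None) -> float:
    """Time (s) of 85% decrease of the amplitude from its max to its min.

    The threshold is ``A_max - 0.85 * (A_max - A_min)`` with the extrema
    taken over the whole record; the crossing is searched only after the
    maximum and located by linear interpolation.  An optional moving-average
    window (samples) smooths the trace first.

    Raises
    ------
    FlatTraceError
        If the trace has no excursion (max == min).
    ThresholdNotReachedError
        If the trace never decays through the threshold.
    """
    if trace.times.size < 3:
        raise ValueError("need at least 3 samples to locate a degradation "
                         "time")
    amps = trace.amplitudes
    if smooth_window is not None:
        amps = _moving_average(amps, int(smooth_window))
    a_max, a_min = float(np.max(amps)), float(np.min(amps))
    if a_max == a_min:
        raise FlatTraceError("amplitude trace is flat; degradation time is "
                             "undefined")
    threshold = a_max - DECREASE_FRACTION * (a_max - a_min)
    i_max = int(np.argmax(amps))

    for i in range(i_max, trace.times.size - 1):
        a0, a1 = amps[i], amps[i + 1]
        if a0 > threshold >= a1:
            t0, t1 = trace.times[i], trace.times[i + 1]
            return float(t0 + (a0 - threshold) / (a0 - a1) * (t1 - t0))
    if amps[i_max] <= threshold:  # degenerate: max itself below threshold
        return float(trace.times[i_max])
    raise ThresholdNotReachedError(
        f"trace never decays through the 85%-decrease threshold "
        f"({threshold:.4g})")


def amplitude_to_concentration(amplitude: float, slope: float,
                               intercept: float = 0.0) -> float:
    """Convert a photoacoustic amplitude to particle concentration (mg/L).

    Inverts the linear calibration ``A = slope * c + intercept``; results
    below zero are floored at 0 (with a warning), since the physical
    concentration cannot be negative.
    """
    if slope <= 0.0:
        raise ValueError(f"calibration slope must be > 0, got {slope}")
    c = (amplitude - intercept) / slope
    if c < 0.0:
        warnings.warn(
            f"amplitude {amplitude} below calibration intercept "
            f"{intercept}; flooring concentration at 0", RuntimeWarning,
            stacklevel=2)
        return 0.0
    return float(c)
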