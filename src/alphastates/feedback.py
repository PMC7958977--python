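"""Offline re-implementation of the real-time neurofeedback dial.

The trainer saw a dial from 0 to 10 driven by frontal alpha power: a 10-s
sliding window of EEG is band-passed at 8-13 Hz, alpha power is computed on
the window's last 2 s, and the dial maps that power linearly between the 2nd
(dial 0) and 98th (dial 10) percentile of the participant's resting alpha
power.  No hardware or rendering here — this exists so the feedback signal
can be simulated and audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import DEFAULT_BAND, PowerSeries, RawEEG, epoch_band_power

__all__ = ["DialCalibration", "FeedbackTrace", "calibrate_dial", "dial_value",
           "sliding_feedback", "online_band_power"]

WINDOW_S = 10.0
POWER_TAIL_S = 2.0


@dataclass(frozen=True)
class DialCalibration:
    """Resting-state alpha-power percentiles anchoring the dial ends (uV^2)."""

    p2: float
    p98: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.p98 > self.p2 >= 0):
            raise ValueError("require p98 > p2 >= 0 (degenerate calibration disallowed)")


@dataclass
class FeedbackTrace:
    """Dial readings over time; first value at t >= window length (10 s)."""

    times: np.ndarray
    dial: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.dial = np.asarray(self.dial, float)
        if self.times.shape != self.dial.shape:
            raise ValueError("times and dial must align")
        if ((self.dial < 0) | (self.dial > 10)).any():
            raise ValueError("dial values must lie in [0, 10]")


def calibrate_dial(resting: PowerSeries | np.ndarray, source: str = "") -> DialCalibration:
    """2nd/98th percentiles (linear interpolation) of resting alpha power.

    At least ~50 epochs are advisable for stable tails; a constant series is
    a degenerate calibration and raises.
    """
    values = resting.values if isinstance(resting, PowerSeries) else np.asarray(resting, float)
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("resting power must contain more than one distinct value")
    p2, p98 = np.percentile(values, [2, 98])
    return DialCalibration(p2=float(p2), p98=float(p98), source=source)


def dial_value(power: float | np.ndarray, calib: DialCalibration) -> float | np.ndarray:
    """Linear map 10 * (power - p2) / (p98 - p2), clipped to [0, 10]."""
    raw = 10.0 * (np.asarray(power, float) - calib.p2) / (calib.p98 - calib.p2)
    out = np.clip(raw, 0.0, 10.0)
    return float(out) if np.isscalar(power) or np.ndim(power) == 0 else out


def _bandpass_sos(sampling_rate: float, band: tuple[float, float], order: int = 4):
    return signal.butter(order, band, btype="bandpass", fs=sampling_rate, output="sos")


def online_band_power(window: np.ndarray, sampling_rate: float,
                      band: tuple[float, float] = DEFAULT_BAND, *, order: int = 4) -> float:
    """Alpha power of the last 2 s of a 10-s window, per the online definition.

    Zero-phase Butterworth band-pass (order 4, logged in the trace config) on
    the full window, then the total alpha-band periodogram power of the final
    2 s per channel, averaged over channels.  Total (not per-bin mean) band
    power is used online so the value is comparable across window lengths and
    equals a^2/2 for an in-band sinusoid of amplitude a.
    """
    window = np.atleast_2d(window)
    sos = _bandpass_sos(sampling_rate, band, order)
    filtered = signal.sosfiltfilt(sos, window, axis=1)
    tail = filtered[:, -int(round(POWER_TAIL_S * sampling_rate)):]
    return float(epoch_band_power(tail[np.newaxis], sampling_rate, band, agg="sum")[0])


def sliding_feedback(
    raw: RawEEG,
    calib: DialCalibration,
    update_interval: float = 1.0,
    band: tuple[float, float] = DEFAULT_BAND,
    *,
    filter_order: int = 4,
) -> FeedbackTrace:
    """Dial trace for a whole stream: one output per hop, first at t = 10 s.

    Each update band-passes the trailing 10-s window, computes alpha power on
    its last 2 s, and maps it through the calibration.  A stream shorter than
    one window is an error.
    """
    if raw.duration < WINDOW_S:
        raise ValueError(f"stream of {raw.duration:.1f} s is shorter than the {WINDOW_S:.0f}-s window")
    fs = raw.sampling_rate
    win = int(round(WINDOW_S * fs))
    hop = int(round(update_interval * fs))
    if hop < 1:
        raise ValueError("update_interval too small for the sampling rate")
    starts = range(0, raw.n_samples - win + 1, hop)
    times, dial = [], []
    for s0 in starts:
        window = raw.samples[:, s0 : s0 + win]
        p = online_band_power(window, fs, band, order=filter_order)
        times.append((s0 + win) / fs)
        dial.append(dial_value(p, calib))
    return FeedbackTrace(times=np.asarray(times), dial=np.asarray(dial))
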