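"""Individualized alpha threshold and binary state symbolization.

Each 1-s epoch is labeled 1 (high alpha state) when its mean alpha power
strictly exceeds an individual threshold, else 0.  The threshold is a
percentage (30/50/70%) of the participant's "maximum alpha power", a robust
cap computed from the session-1 resting eyes-open power distribution and
reused for all of that participant's sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .preprocess import PowerSeries

__all__ = ["ThresholdSpec", "compute_max_power", "compute_threshold", "symbolize"]

THRESHOLD_PERCENTS = (30.0, 50.0, 70.0)


@dataclass(frozen=True)
class ThresholdSpec:
    """A resolved symbolization threshold: percent/100 x max_power, with provenance."""

    percent: float
    max_power: float
    threshold: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.max_power < 0:
            raise ValueError("max_power must be non-negative")
        if abs(self.threshold - self.percent / 100.0 * self.max_power) > 1e-9 * max(1.0, self.max_power):
            raise ValueError("threshold must equal percent/100 * max_power")


def compute_max_power(
    resting: PowerSeries | np.ndarray,
    convention: Literal["tukey_fence", "literal_iqr"] = "tukey_fence",
) -> float:
    """Robust maximum of the resting alpha-power distribution.

    The "1.5 x interquartile range" rule is read as the Tukey upper fence
    Q3 + 1.5 x IQR (default): a literal 1.5 x IQR alone is not a power level
    and can fall below the median, defeating its purpose of capping random
    high-amplitude fluctuations.  The literal product is available as
    ``convention="literal_iqr"``.  Quantiles use linear interpolation.
    """
    values = resting.values if isinstance(resting, PowerSeries) else np.asarray(resting, float)
    if values.size < 4:
        raise ValueError(f"need at least 4 resting epochs to estimate quartiles, got {values.size}")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if convention == "tukey_fence":
        return float(q3 + 1.5 * iqr)
    if convention == "literal_iqr":
        return float(1.5 * iqr)
    raise ValueError(f"unknown max-power convention {convention!r}")


def compute_threshold(max_power: float, percent: float = 30.0, source: str = "") -> ThresholdSpec:
    """Threshold at `percent`% of `max_power` (percent in (0, 100])."""
    if not (0 < percent <= 100):
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    if max_power < 0:
        raise ValueError("max_power must be non-negative")
    return ThresholdSpec(percent=float(percent), max_power=float(max_power),
                         threshold=float(percent) / 100.0 * float(max_power), source=source)


def symbolize(power: PowerSeries | np.ndarray, spec: ThresholdSpec | float) -> np.ndarray:
    """Binary state per epoch: 1 iff power strictly exceeds the threshold (ties -> 0).

    Rejected epochs have already been dropped from the PowerSeries, so the
    symbol sequence is the concatenation over retained epochs.
    """
    values = power.values if isinstance(power, PowerSeries) else np.asarray(power, float)
    if values.size == 0:
        raise ValueError("power series is empty")
    thr = spec.threshold if isinstance(spec, ThresholdSpec) else float(spec)
    return (values > thr).astype(np.int8)
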