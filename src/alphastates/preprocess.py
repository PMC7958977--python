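"""Raw EEG to per-epoch alpha-band power.

The offline chain: anti-aliased downsampling to 250 Hz, segmentation into
1-s non-overlapping epochs, deterministic peak-amplitude artifact rejection,
and per-epoch band power by rectangular-window periodogram averaged over the
8-13 Hz bins (inclusive) and over the two frontal channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "RawEEG",
    "PowerSeries",
    "ArtifactRateWarning",
    "downsample",
    "segment_epochs",
    "reject_artifact_epochs",
    "alpha_power",
]

DEFAULT_BAND = (8.0, 13.0)
DEFAULT_CHANNELS = ("AF3", "AF4")


class ArtifactRateWarning(UserWarning):
    """More epochs flagged as artifacts than a usable recording should contain."""


@dataclass
class RawEEG:
    """A multi-channel EEG recording: `samples` is channels x time in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but {len(self.channel_labels)} labels"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def pick(self, labels: list[str] | tuple[str, ...]) -> "RawEEG":
        """Channel subset in the requested order; unknown labels raise with the available ones."""
        idx = []
        for lab in labels:
            if lab not in self.channel_labels:
                raise KeyError(
                    f"channel {lab!r} not present; available: {self.channel_labels}"
                )
            idx.append(self.channel_labels.index(lab))
        return RawEEG(self.samples[idx], self.sampling_rate, list(labels))


@dataclass
class PowerSeries:
    """Mean alpha-band power per retained 1-s epoch (uV^2).

    ``rejected_mask`` has one entry per *original* epoch; ``values`` holds
    only the retained epochs, in order.
    """

    values: np.ndarray
    epoch_duration: float = 1.0
    rejected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("power values must be non-negative")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        if int(np.sum(~self.rejected_mask)) != self.values.size:
            raise ValueError("values length must equal number of retained epochs")

    @property
    def n_epochs(self) -> int:
        return self.values.size


def downsample(raw: RawEEG, target_rate: float = 250.0) -> RawEEG:
    """Anti-alias low-pass and decimate to `target_rate` (integer factor required).

    Uses a zero-phase FIR decimator so amplitudes of sub-Nyquist components
    are preserved; the identity factor returns the signal unchanged.
    """
    factor = raw.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {raw.sampling_rate} is not an integer multiple of {target_rate}"
        )
    factor = int(round(factor))
    if factor == 1:
        return RawEEG(raw.samples.copy(), target_rate, list(raw.channel_labels))
    out = signal.decimate(raw.samples, factor, ftype="fir", axis=1, zero_phase=True)
    return RawEEG(out, target_rate, list(raw.channel_labels))


def segment_epochs(raw: RawEEG, epoch_duration: float = 1.0) -> np.ndarray:
    """Split into non-overlapping epochs: array (n_epochs, n_channels, samples_per_epoch).

    A trailing partial epoch is discarded; a recording shorter than one epoch
    is an error.
    """
    spe = int(round(raw.sampling_rate * epoch_duration))
    n_epochs = raw.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording of {raw.n_samples} samples is shorter than one "
            f"{epoch_duration}-s epoch at {raw.sampling_rate} Hz"
        )
    trimmed = raw.samples[:, : n_epochs * spe]
    return np.moveaxis(trimmed.reshape(raw.samples.shape[0], n_epochs, spe), 1, 0)


def reject_artifact_epochs(
    epochs: np.ndarray, amplitude_criterion: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag epochs whose peak absolute amplitude exceeds the criterion (uV).

    Returns ``(retained_epochs, rejected_mask)``.  Replaces manual visual
    inspection with a deterministic rule; warns if more than 10% of epochs
    are flagged, since the recordings being emulated discarded at most 10%.
    """
    if amplitude_criterion <= 0:
        raise ValueError("amplitude criterion must be positive")
    peaks = np.abs(epochs).max(axis=(1, 2))
    mask = peaks > amplitude_criterion
    frac = mask.mean() if mask.size else 0.0
    if frac > 0.10:
        warnings.warn(
            f"{frac:.1%} of epochs exceed {amplitude_criterion} uV (rejection rate above 10%)",
            ArtifactRateWarning,
            stacklevel=2,
        )
    return epochs[~mask], mask


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)  # inclusive edges


def epoch_band_power(
    epochs: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    *,
    window: str = "boxcar",
    agg: str = "mean",
) -> np.ndarray:
    """Band power per epoch: periodogram per channel, `agg` over band bins, mean over channels.

    ``agg="mean"`` (default) averages power over the frequency bins inside the
    band; ``agg="sum"`` totals it, which is comparable across window lengths.
    """
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
    nyq = sampling_rate / 2
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    freqs, pxx = signal.periodogram(
        epochs, fs=sampling_rate, window=window, scaling="spectrum", axis=-1
    )
    sel = _band_bins(freqs, band)
    if not sel.any():
        raise ValueError(f"no periodogram bins fall inside band {band}")
    if agg == "mean":
        band_pow = pxx[..., sel].mean(axis=-1)
    elif agg == "sum":
        band_pow = pxx[..., sel].sum(axis=-1)
    else:
        raise ValueError(f"unknown bin aggregation {agg!r}")
    return band_pow.mean(axis=1)  # mean over channels


def alpha_power(
    epochs: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    *,
    rejected_mask: np.ndarray | None = None,
    window: str = "boxcar",
    agg: str = "mean",
) -> PowerSeries:
    """Per-epoch mean alpha-band power as a :class:`PowerSeries`.

    On 1-s epochs at 250 Hz the rectangular-window periodogram has 1-Hz bin
    spacing, so the default 8-13 Hz band (both edges inclusive) covers six
    bins.  `epochs` are the retained epochs; `rejected_mask` (if given) keeps
    the bookkeeping of where the discarded ones were.
    """
    values = epoch_band_power(epochs, sampling_rate, band, window=window, agg=agg)
    return PowerSeries(values=values, epoch_duration=epochs.shape[-1] / sampling_rate,
                       rejected_mask=rejected_mask)


def power_pipeline(
    raw: RawEEG,
    *,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    target_rate: float = 250.0,
    epoch_duration: float = 1.0,
    band: tuple[float, float] = DEFAULT_BAND,
    artifact_criterion: float = 100.0,
    window: str = "boxcar",
    agg: str = "mean",
) -> PowerSeries:
    """Full offline chain: pick channels, downsample, epoch, reject, band power."""
    picked = raw.pick(channels) if channels else raw
    ds = downsample(picked, target_rate) if picked.sampling_rate != target_rate else picked
    epochs = segment_epochs(ds, epoch_duration)
    retained, mask = reject_artifact_epochs(epochs, artifact_criterion)
    if retained.shape[0] == 0:
        raise ValueError("all epochs were rejected as artifacts")
    return alpha_power(retained, ds.sampling_rate, band,
                       rejected_mask=mask, window=window, agg=agg)
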