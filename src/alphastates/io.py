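"""Reading and writing EEG recordings and tabular outputs.

Two on-disk EEG representations are supported: European Data Format (read
via :mod:`mne`, when installed) and a self-describing delimited-text dialect
whose header comment lines carry the sampling rate and channel labels —
handy as a zero-dependency, diff-able fixture format.  Text output only; no
EDF writer is provided.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import RawEEG

__all__ = ["read_eeg", "write_eeg_text", "read_eeg_text", "read_eeg_edf"]

_TEXT_SUFFIXES = {".txt", ".tsv", ".csv"}


def write_eeg_text(raw: RawEEG, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write a recording as delimited text: header comments, then samples by rows.

    Layout::

        # sampling_rate_hz: 1000
        # channels: AF3\tAF4
        <sample row per time point, one column per channel>
    """
    path = Path(path)
    header = (f"sampling_rate_hz: {raw.sampling_rate:g}\n"
              f"channels: " + "\t".join(raw.channel_labels))
    np.savetxt(path, raw.samples.T, fmt=fmt, delimiter="\t", header=header)
    return path


def read_eeg_text(path: str | Path, channels: list[str] | None = None) -> RawEEG:
    """Read the delimited-text dialect written by :func:`write_eeg_text`."""
    path = Path(path)
    rate = None
    labels: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("sampling_rate_hz:"):
                try:
                    rate = float(body.split(":", 1)[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable sampling rate") from exc
            elif body.startswith("channels:"):
                labels = body.split(":", 1)[1].split()
    if rate is None or labels is None:
        raise ValueError(f"{path}: header must declare sampling_rate_hz and channels")
    data = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {data.shape[1]} sample columns but {len(labels)} channel labels"
        )
    raw = RawEEG(samples=data.T, sampling_rate=rate, channel_labels=labels)
    return raw.pick(channels) if channels else raw


def read_eeg_edf(path: str | Path, channels: list[str] | None = None) -> RawEEG:
    """Read a European Data Format recording (requires :mod:`mne`).

    Values are converted from MNE's volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the 'mne' package") from exc
    edf = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    raw = RawEEG(
        samples=edf.get_data() * 1e6,
        sampling_rate=float(edf.info["sfreq"]),
        channel_labels=list(edf.ch_names),
    )
    return raw.pick(channels) if channels else raw


def read_eeg(path: str | Path, channels: list[str] | None = None) -> RawEEG:
    """Dispatch on extension: ``.edf`` via mne, text suffixes via the dialect reader."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path, channels)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return read_eeg_text(path, channels)
    raise ValueError(f"unrecognized EEG file extension {path.suffix!r}")
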