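"""Minimal EDF (European Data Format) writer and an MNE-backed reader.

The writer emits plain 16-bit EDF: one data record per second, physical
units µV, per-channel symmetric physical range.  It covers exactly what
the cohort writer needs (continuous multichannel signals with labelled
channels); annotations, EDF+ discontinuities and non-uniform record
layouts are out of scope.  Reading goes through :func:`mne.io.read_raw_edf`
so the round trip is checked against an independent parser.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]

_DIG_MAX = 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    signal: np.ndarray,
    channel_labels: list[str] | tuple[str, ...],
    sampling_rate: float,
    patient_id: str = "X",
    recording_id: str = "synthetic session",
) -> None:
    """Write channels x samples data (µV) as 16-bit EDF.

    The sampling rate must be a whole number (samples per 1 s record); the
    final record is zero-padded when the signal length is not a multiple
    of the rate.
    """
    fs = int(sampling_rate)
    if fs != sampling_rate:
        raise ValueError("EDF writer requires an integer sampling rate")
    signal = np.asarray(signal, dtype=np.float64)
    n_ch, n_samples = signal.shape
    if n_ch != len(channel_labels):
        raise ValueError("channel_labels length does not match signal")
    n_records = int(np.ceil(n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samples] = signal

    # symmetric per-channel physical range, integer µV bounds for clean ascii
    pm = np.ceil(np.abs(padded).max(axis=1)).astype(int)
    pm = np.maximum(pm, 1)
    gains = pm / _DIG_MAX
    digital = np.round(padded / gains[:, None]).clip(-_DIG_MAX, _DIG_MAX).astype("<i2")

    header = bytearray()
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field("01.01.01", 8)
    header += _field("00.00.00", 8)
    header += _field(256 * (n_ch + 1), 8)
    header += _field("", 44)
    header += _field(n_records, 8)
    header += _field(1, 8)
    header += _field(n_ch, 4)
    for getter, width in (
        (lambda i: channel_labels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: -pm[i], 8),
        (lambda i: pm[i], 8),
        (lambda i: -_DIG_MAX, 8),
        (lambda i: _DIG_MAX, 8),
        (lambda i: "", 80),
        (lambda i: fs, 8),
        (lambda i: "", 32),
    ):
        for i in range(n_ch):
            header += _field(getter(i), width)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records: per record, channel-sequential sample blocks
        view = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(view).tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (channels x samples in µV, labels, rate)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> µV
    return data, list(raw.ch_names), float(raw.info["sfreq"])
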