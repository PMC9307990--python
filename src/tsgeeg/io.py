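"""Reading and writing recordings: NPZ matrices, EDF, dataset manifests.

EDF reading goes through MNE.  EDF writing is a minimal 16-bit EDF encoder
implemented here (one-second data records, microvolt physical units),
sufficient for exporting synthetic cohorts in a form any EDF reader
accepts; it is not a general-purpose EDF+ writer.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecording

__all__ = [
    "save_npz", "load_npz", "write_edf", "read_edf",
    "read_manifest", "load_dataset", "load_recording",
]


def save_npz(recording: EEGRecording, path) -> None:
    np.savez(
        path,
        signal=recording.signal,
        sampling_rate=recording.sampling_rate,
        channel_labels=np.array(recording.channel_labels),
        label=-1 if recording.label is None else int(recording.label),
        subject_id=recording.subject_id,
        session_id=recording.session_id,
    )


def load_npz(path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as data:
        label = int(data["label"])
        return EEGRecording(
            signal=data["signal"],
            sampling_rate=float(data["sampling_rate"]),
            channel_labels=[str(c) for c in data["channel_labels"]],
            label=None if label < 0 else label,
            subject_id=str(data["subject_id"]),
            session_id=str(data["session_id"]),
        )


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    for precision in range(6, -1, -1):
        s = f"{value:.{precision}g}"
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(recording: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    Requires an integer sampling rate.  The last record is zero-padded if
    the signal length is not a whole number of seconds.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_c, T = recording.signal.shape
    n_records = math.ceil(T / fs)
    padded = np.zeros((n_c, n_records * fs))
    padded[:, :T] = recording.signal

    # physical range: rounded to 4 significant digits (with margin) so the
    # header string and the scaling factor are exactly the same number
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    phys_max = np.array([float(f"{v * 1.001:.4g}") for v in phys_max])
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(f"subject {recording.subject_id}", 80),
        _ascii_field(f"session {recording.session_id} label "
                     f"{recording.label}", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(str(256 * (1 + n_c)), 8),
        _ascii_field("", 44),
        _ascii_field(str(n_records), 8),
        _ascii_field("1", 8),
        _ascii_field(str(n_c), 4),
    ])
    sig_headers = b"".join([
        b"".join(_ascii_field(lbl, 16) for lbl in recording.channel_labels),
        b"".join(_ascii_field("", 80) for _ in range(n_c)),
        b"".join(_ascii_field("uV", 8) for _ in range(n_c)),
        b"".join(_num_field(-pm, 8) for pm in phys_max),
        b"".join(_num_field(pm, 8) for pm in phys_max),
        b"".join(_ascii_field(dig_min, 8) for _ in range(n_c)),
        b"".join(_ascii_field(dig_max, 8) for _ in range(n_c)),
        b"".join(_ascii_field("", 80) for _ in range(n_c)),
        b"".join(_ascii_field(fs, 8) for _ in range(n_c)),
        b"".join(_ascii_field("", 32) for _ in range(n_c)),
    ])

    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.round((padded + phys_max[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path, label: int | None = None, subject_id: str = "S00",
             session_id: str = "0") -> EEGRecording:
    """Read an EDF/EDF+ file via MNE; signal returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        signal=raw.get_data() * 1e6,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        label=label, subject_id=subject_id, session_id=session_id,
    )


def load_recording(path, label: int | None = None, subject_id: str = "S00",
                   session_id: str = "0") -> EEGRecording:
    """Load a recording by file extension (.npz, .edf, or a CSV matrix).

    CSV files are read as an ``n_channels x n_samples`` numeric matrix with
    no header; the sampling rate must then be stored elsewhere (the
    manifest), so CSV input goes through :func:`load_dataset`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        rec = load_npz(path)
        if label is not None:
            rec.label = label
        rec.subject_id, rec.session_id = subject_id, session_id
        return rec
    if suffix == ".edf":
        return read_edf(path, label=label, subject_id=subject_id,
                        session_id=session_id)
    raise ValueError(f"unsupported recording format: {path.suffix}")


def read_manifest(path) -> pd.DataFrame:
    """Dataset manifest CSV: subject_id, session_id, path, label[, fs]."""
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    required = {"subject_id", "session_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def load_dataset(manifest_path) -> list[EEGRecording]:
    """Load every recording listed in a manifest CSV.

    Relative paths are resolved against the manifest's directory.  A ``fs``
    column provides the sampling rate for bare CSV signal matrices.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    recordings = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        if p.suffix.lower() == ".csv":
            signal = np.loadtxt(p, delimiter=",", ndmin=2)
            fs = float(getattr(row, "fs"))
            rec = EEGRecording(signal=signal, sampling_rate=fs,
                               label=int(row.label),
                               subject_id=str(row.subject_id),
                               session_id=str(row.session_id))
        else:
            rec = load_recording(p, label=int(row.label),
                                 subject_id=str(row.subject_id),
                                 session_id=str(row.session_id))
        recordings.append(rec)
    return recordings
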