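"""Filtering and windowing of multichannel EEG recordings.

A recording is an ``n_channels x n_samples`` signal with a sampling rate and
optional class label.  Analysis operates on fixed-length, possibly
overlapping windows cut from the (band-pass filtered) recording; all feature
extraction downstream is per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = ["EEGRecording", "WindowSet", "bandpass_filter", "window_series"]

#: 19-channel 10-20 montage used by default for synthetic cohorts.  The
#: leading letter encodes the scalp region (F frontal, T temporal, C central,
#: P parietal, O occipital).
STANDARD_1020_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

_REGION_BY_LETTER = {
    "F": "frontal", "T": "temporal", "C": "central",
    "P": "parietal", "O": "occipital",
}


def channel_region(label: str) -> str:
    """Scalp region ("frontal", "temporal", ...) for a 10-20 channel label."""
    return _REGION_BY_LETTER.get(label[:1].upper(), "unknown")


def _default_labels(n_channels: int) -> list[str]:
    if n_channels <= len(STANDARD_1020_19):
        return list(STANDARD_1020_19[:n_channels])
    return [f"ch{i:02d}" for i in range(n_channels)]


@dataclass
class EEGRecording:
    """A multichannel EEG signal with metadata.

    Parameters
    ----------
    signal : ndarray of shape (n_channels, n_samples)
        The raw (or filtered) waveform, microvolts or arbitrary units.
    sampling_rate : float
        Samples per second (Hz).
    channel_labels : list of str, optional
        One label per channel; defaults to the 10-20 montage prefix.
    label : int or None
        Optional two-class condition label (0/1).
    subject_id, session_id : str
        Provenance identifiers used by the experiment protocols.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    label: int | None = None
    subject_id: str = "S00"
    session_id: str = "0"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (n_channels, n_samples) array")
        n_c, T = self.signal.shape
        if n_c < 2:
            raise ValueError(f"need at least 2 channels, got {n_c}")
        if T < 2:
            raise ValueError(f"need at least 2 samples, got {T}")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = _default_labels(n_c)
        if len(self.channel_labels) != n_c:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class WindowSet:
    """Contiguous windows cut from one recording.

    ``windows`` has shape ``(n_windows, n_channels, window_size)``; window k
    starts at sample ``k * (window_size - overlap)`` of the source signal and
    consecutive windows share exactly ``overlap`` samples.  Trailing samples
    that do not fill a whole window are dropped.
    """

    windows: np.ndarray
    window_size: int
    overlap: int
    labels: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def bandpass_filter(
    recording: EEGRecording, low_hz: float, high_hz: float, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    A 4th-order Butterworth filter is run forward and backward
    (``sosfiltfilt``) so that phase — and hence inter-channel correlation
    structure — is preserved.  ``low_hz = 0`` degenerates to a pure low-pass.
    """
    nyq = recording.sampling_rate / 2.0
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz is at or above Nyquist {nyq} Hz")
    if low_hz > 0:
        sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=recording.sampling_rate, output="sos")
    else:
        sos = sps.butter(order, high_hz, btype="lowpass",
                         fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=-1)
    return replace(recording, signal=np.ascontiguousarray(filtered))


def window_series(recording: EEGRecording, w: int, h: int = 0) -> WindowSet:
    """Split a recording into ``n_w = floor((T - h) / (w - h))`` windows.

    Parameters
    ----------
    w : int
        Window size in samples.
    h : int
        Overlap between consecutive windows, in samples (``0 <= h < w``).
    """
    w, h = int(w), int(h)
    T = recording.n_samples
    if not 0 <= h < w:
        raise ValueError(f"overlap must satisfy 0 <= h < w, got h={h}, w={w}")
    if w > T:
        raise ValueError(f"window size {w} exceeds recording length {T}: no windows")
    step = w - h
    n_w = (T - h) // step
    starts = np.arange(n_w) * step
    windows = np.stack([recording.signal[:, s:s + w] for s in starts])
    labels = np.full(n_w, -1 if recording.label is None else recording.label)
    return WindowSet(
        windows=windows, window_size=w, overlap=h, labels=labels,
        sampling_rate=recording.sampling_rate,
        channel_labels=list(recording.channel_labels),
    )
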