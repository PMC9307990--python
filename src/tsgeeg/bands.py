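"""Band-power (BF) features: Welch PSD, per-channel normalized band masses, PCA.

For every window and channel the power spectral density is estimated and
integrated over a fixed set of non-overlapping frequency bands.  Band powers
are normalized per channel to sum to 1 (removing overall amplitude), the
``n_channels x n_bands`` matrix is flattened channel-major, and the
resulting vectors are projected to a low dimension with PCA whose rank is
chosen at the second scree elbow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .dimension import select_dimension

__all__ = [
    "Band", "BandScheme", "default_scheme",
    "estimate_band_powers", "normalize_and_flatten",
    "BandPowerTransformer", "fit_projector",
]


@dataclass(frozen=True)
class Band:
    name: str
    f_low: float
    f_high: float


class BandScheme:
    """Ordered, non-overlapping frequency bands.

    Band membership of a PSD bin at frequency f is half-open,
    ``f_low <= f < f_high``, so schemes whose edges touch (e.g. mid beta
    20.0-25.0 next to high beta 25.0-30.0) never double-count a bin.
    """

    def __init__(self, bands: list[tuple[str, float, float]]):
        parsed = [Band(str(n), float(lo), float(hi)) for n, lo, hi in bands]
        for b in parsed:
            if not b.f_low < b.f_high:
                raise ValueError(f"band {b.name}: need f_low < f_high")
        for a, b in zip(parsed, parsed[1:]):
            if b.f_low < a.f_high:
                raise ValueError(f"bands {a.name} and {b.name} overlap")
        self.bands = parsed

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def max_frequency(self) -> float:
        return self.bands[-1].f_high


def default_scheme() -> BandScheme:
    """The 8-band theta/alpha/beta split used throughout."""
    return BandScheme([
        ("theta_low", 4.1, 5.8),
        ("theta_high", 5.9, 7.4),
        ("alpha_low", 7.4, 8.9),
        ("alpha_mid", 9.0, 11.0),
        ("alpha_high", 11.1, 12.9),
        ("beta_low", 13.0, 19.9),
        ("beta_mid", 20.0, 25.0),
        ("beta_high", 25.0, 30.0),
    ])


def estimate_band_powers(
    window: np.ndarray, sampling_rate: float, scheme: BandScheme | None = None
) -> np.ndarray:
    """Per-channel band powers of one ``(n_channels, w)`` window.

    PSD is estimated with Welch's method (Hann taper, segment length
    ``min(w, sampling_rate)`` samples, 50% segment overlap) and integrated
    over each band.  Returns an ``(n_channels, n_bands)`` non-negative
    matrix.
    """
    scheme = scheme or default_scheme()
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] < 2:
        raise ValueError("window must be (n_channels, w) with w >= 2")
    if scheme.max_frequency > sampling_rate / 2:
        raise ValueError(
            f"band edge {scheme.max_frequency} Hz above Nyquist {sampling_rate / 2} Hz"
        )
    w = window.shape[1]
    nperseg = min(w, int(round(sampling_rate)))
    freqs, psd = sps.welch(
        window, fs=sampling_rate, window="hann",
        nperseg=nperseg, noverlap=nperseg // 2, axis=-1,
    )
    df = freqs[1] - freqs[0]
    out = np.empty((window.shape[0], len(scheme)))
    for i, band in enumerate(scheme):
        mask = (freqs >= band.f_low) & (freqs < band.f_high)
        out[:, i] = psd[:, mask].sum(axis=-1) * df
    return out


def normalize_and_flatten(powers: np.ndarray) -> np.ndarray:
    """Normalize band powers per channel and flatten channel-major.

    ``powers`` is ``(n_windows, n_channels, n_bands)`` (a single window may
    be passed as ``(n_channels, n_bands)``).  Each channel's bands are
    divided by their sum so every channel block sums to 1; a channel with
    zero total in-scheme power gets a uniform ``1/n_bands`` block and a
    warning.  Returns ``(n_windows, n_channels * n_bands)``.
    """
    powers = np.asarray(powers, dtype=float)
    single = powers.ndim == 2
    if single:
        powers = powers[None]
    n_w, n_c, I = powers.shape
    totals = powers.sum(axis=-1, keepdims=True)
    zero = totals <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} channel-window(s) with zero in-scheme power; "
            "using uniform band features for them",
            RuntimeWarning, stacklevel=2,
        )
    normalized = np.where(zero, 1.0 / I, powers / np.where(zero, 1.0, totals))
    flat = normalized.reshape(n_w, n_c * I)
    return flat[0] if single else flat


def band_feature_names(channel_labels: list[str], scheme: BandScheme) -> list[str]:
    return [f"{ch}_{b}" for ch in channel_labels for b in scheme.names]


class BandPowerTransformer(TransformerMixin, BaseEstimator):
    """BF feature map: normalized band powers followed by a PCA projection.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate of the windows (ignored when ``precomputed``).
    scheme : BandScheme, optional
        Frequency bands; defaults to the 8-band theta/alpha/beta scheme.
    n_elbows : int, default 2
        Which scree elbow of the PCA singular values sets the output
        dimension.
    n_components : int, optional
        Fixed output dimension, overriding elbow selection.
    precomputed : bool, default False
        If True, ``X`` is an already-normalized ``(n_windows, n_c * I)``
        feature matrix instead of a stack of raw windows.

    Attributes
    ----------
    pca_ : sklearn PCA fitted on the training band features.
    n_components_ : int, the selected output dimension.
    singular_values_ : full PCA singular-value spectrum.
    """

    def __init__(self, sampling_rate: float = 1.0, scheme: BandScheme | None = None,
                 n_elbows: int = 2, n_components: int | None = None,
                 precomputed: bool = False):
        self.sampling_rate = sampling_rate
        self.scheme = scheme
        self.n_elbows = n_elbows
        self.n_components = n_components
        self.precomputed = precomputed

    def _band_features(self, X: np.ndarray) -> np.ndarray:
        if self.precomputed:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("precomputed features must be 2-D")
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, w)")
        scheme = self.scheme or default_scheme()
        powers = np.stack(
            [estimate_band_powers(win, self.sampling_rate, scheme) for win in X]
        )
        return normalize_and_flatten(powers)

    def fit(self, X, y=None):
        F = self._band_features(X)
        if F.shape[0] < 3:
            raise ValueError("need at least 3 windows to fit the projector")
        if not np.any(F.std(axis=0) > 0):
            raise ValueError("training features have rank 0")
        pca = PCA()
        pca.fit(F)
        if self.n_components is not None:
            d = int(self.n_components)
            if not 1 <= d <= len(pca.singular_values_):
                raise ValueError(f"n_components {d} out of range")
        else:
            d = select_dimension(pca.singular_values_, n_elbows=self.n_elbows)
        self.singular_values_ = pca.singular_values_.copy()
        self.pca_ = pca
        self.n_components_ = d
        self.components_ = pca.components_[:d]
        self.mean_ = pca.mean_
        self.n_features_in_ = F.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        F = self._band_features(X)
        if F.shape[1] != self.n_features_in_:
            raise ValueError("feature-length mismatch with training data")
        return (F - self.mean_) @ self.components_.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return np.asarray(Z) @ self.components_ + self.mean_


def fit_projector(train_features: np.ndarray, n_elbows: int = 2,
                  n_components: int | None = None) -> BandPowerTransformer:
    """Fit the PCA projector on an already-normalized BF feature matrix."""
    return BandPowerTransformer(
        precomputed=True, n_elbows=n_elbows, n_components=n_components
    ).fit(train_features)
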