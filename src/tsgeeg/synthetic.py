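"""Synthetic labeled EEG cohorts with controllable class structure.

Each channel is a sum of three parts:

* band-limited oscillations — per channel and per frequency band, white
  noise band-pass filtered to the band's edges and amplitude-scaled so the
  channel's relative band powers follow ``band_power_profile`` (total
  oscillation variance ``osc_power``);
* shared latent factors — ``q`` low-frequency noise processes common to all
  channels of a recording, mixed through ``latent_factor_loadings``; these
  induce class-conditional inter-channel correlation and, when loadings
  differ between classes only in sign, leave every marginal spectrum
  untouched;
* independent white measurement noise of standard deviation ``noise_sd``.

Two-class differences can therefore be planted in the band-power profiles
(detectable by BF features), in the correlation structure (detectable by
TSG features), in both, or in neither.  Preset spec factories for these
four study conditions are provided.  Cohorts add per-subject multiplicative
jitter of the band profiles (a subject-level trait, shared by both classes)
to create inter-subject distribution shift for the transfer protocols.

Not modelled: eye blinks, muscle artifacts, 1/f background, electrode
drift — this is a fixture generator for the feature pipelines, not a
physiological simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bands import BandScheme, default_scheme
from .preprocess import EEGRecording

__all__ = [
    "SyntheticClassSpec", "SyntheticCohortConfig",
    "generate_recording", "generate_cohort",
    "null_specs", "correlation_effect_specs", "band_effect_specs",
    "combined_effect_specs", "planted_channel_specs",
]

#: Frequency band (Hz) of the shared latent factor processes; inside the
#: 0.5-30 Hz analysis band so factor-induced correlation survives filtering.
FACTOR_BAND = (4.0, 12.0)


@dataclass
class SyntheticClassSpec:
    """Generative parameters of one class condition.

    Parameters
    ----------
    band_power_profile : (n_channels, n_bands) array
        Relative band powers; each row is non-negative and sums to 1.
    latent_factor_loadings : (n_channels, q) array
        Mixing weights of the q shared factor processes.
    noise_sd : float
        Standard deviation of the independent white noise.
    label : int
        Class identifier (0/1).
    osc_power : float
        Total variance of the per-channel oscillation mixture; 0 switches
        the independent oscillations off entirely.
    """

    band_power_profile: np.ndarray
    latent_factor_loadings: np.ndarray
    noise_sd: float
    label: int
    osc_power: float = 1.0

    def __post_init__(self) -> None:
        self.band_power_profile = np.asarray(self.band_power_profile, dtype=float)
        self.latent_factor_loadings = np.asarray(
            self.latent_factor_loadings, dtype=float
        )
        if self.band_power_profile.ndim != 2:
            raise ValueError("band_power_profile must be (n_channels, n_bands)")
        if np.any(self.band_power_profile < 0):
            raise ValueError("band_power_profile entries must be non-negative")
        sums = self.band_power_profile.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("band_power_profile rows must sum to 1 (tol 1e-9)")
        if self.latent_factor_loadings.ndim != 2:
            raise ValueError("latent_factor_loadings must be (n_channels, q)")
        if self.latent_factor_loadings.shape[1] < 1:
            raise ValueError("need q >= 1 factor columns")
        if self.latent_factor_loadings.shape[0] != self.band_power_profile.shape[0]:
            raise ValueError("loadings and profile channel counts differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.osc_power < 0:
            raise ValueError("osc_power must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.band_power_profile.shape[0]


@dataclass
class SyntheticCohortConfig:
    """Shape and randomness of a synthetic cohort.

    Defaults mirror a Mental-Math-shaped study: 36 subjects, one session
    each, 19 channels, one recording per class per session.
    """

    class_specs: tuple[SyntheticClassSpec, SyntheticClassSpec]
    n_subjects: int = 36
    n_sessions_per_subject: int = 1
    n_channels: int = 19
    sampling_rate: float = 128.0
    duration_per_class: float = 180.0
    subject_jitter: float = 0.1
    seed: int = 0
    scheme: BandScheme | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.sampling_rate <= 0 or self.duration_per_class <= 0:
            raise ValueError("sampling_rate and duration_per_class must be positive")
        if len(self.class_specs) != 2:
            raise ValueError("class_specs must be a pair")
        for spec in self.class_specs:
            if spec.n_channels != self.n_channels:
                raise ValueError("class spec channel count != config n_channels")


_GAIN_CACHE: dict[tuple, float] = {}


def _filtfilt_gain(sos: np.ndarray, key: tuple) -> float:
    """RMS output amplitude of zero-phase filtering applied to unit white noise.

    Forward-backward filtering has magnitude response |H|^2, so the output
    variance is the frequency average of |H|^4.  Using this *theoretical*
    gain (rather than the realized standard deviation of each draw) keeps
    disjoint windows of a recording statistically independent; normalizing
    by the realized sd would pin the total realized power of every
    recording, negatively correlating held-out windows with training
    windows of the same recording.
    """
    if key not in _GAIN_CACHE:
        _, h = sps.sosfreqz(sos, worN=8192)
        _GAIN_CACHE[key] = float(np.sqrt(np.mean(np.abs(h) ** 4)))
    return _GAIN_CACHE[key]


def _bandlimited_noise(rng: np.random.Generator, n_samples: int,
                       band: tuple[float, float], fs: float) -> np.ndarray:
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    gain = _filtfilt_gain(sos, (lo, hi, fs))
    return sps.sosfiltfilt(sos, rng.standard_normal(n_samples)) / gain


def generate_recording(
    spec: SyntheticClassSpec,
    n_channels: int,
    sampling_rate: float,
    duration: float,
    seed,
    scheme: BandScheme | None = None,
    subject_id: str = "S00",
    session_id: str = "0",
) -> EEGRecording:
    """One labeled synthetic recording; bit-deterministic given ``seed``."""
    if sampling_rate <= 0 or duration <= 0:
        raise ValueError("sampling_rate and duration must be positive")
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if n_channels != spec.n_channels:
        raise ValueError("n_channels does not match the class spec")
    scheme = scheme or default_scheme()
    if spec.band_power_profile.shape[1] != len(scheme):
        raise ValueError("profile band count does not match the band scheme")
    if scheme.max_frequency >= sampling_rate / 2:
        raise ValueError("band scheme extends to or beyond Nyquist")
    T = int(round(duration * sampling_rate))
    if T < 2 * n_channels:
        raise ValueError("duration too short: need >= 2 samples per channel")
    rng = np.random.default_rng(seed)
    signal = np.zeros((n_channels, T))
    if spec.osc_power > 0:
        amps = np.sqrt(spec.osc_power * spec.band_power_profile)
        for i, band in enumerate(scheme):
            col = amps[:, i]
            if not np.any(col > 0):
                continue
            for j in np.nonzero(col > 0)[0]:
                signal[j] += col[j] * _bandlimited_noise(
                    rng, T, (band.f_low, band.f_high), sampling_rate
                )
    q = spec.latent_factor_loadings.shape[1]
    if np.any(spec.latent_factor_loadings != 0):
        factors = np.stack([
            _bandlimited_noise(rng, T, FACTOR_BAND, sampling_rate)
            for _ in range(q)
        ])
        signal += spec.latent_factor_loadings @ factors
    if spec.noise_sd > 0:
        signal += spec.noise_sd * rng.standard_normal((n_channels, T))
    return EEGRecording(
        signal=signal, sampling_rate=sampling_rate, label=int(spec.label),
        subject_id=subject_id, session_id=session_id,
    )


def _jittered(spec: SyntheticClassSpec, eps: np.ndarray) -> SyntheticClassSpec:
    profile = spec.band_power_profile * (1.0 + eps)
    profile = np.clip(profile, 1e-12, None)
    profile /= profile.sum(axis=1, keepdims=True)
    return SyntheticClassSpec(
        band_power_profile=profile,
        latent_factor_loadings=spec.latent_factor_loadings.copy(),
        noise_sd=spec.noise_sd, label=spec.label, osc_power=spec.osc_power,
    )


def generate_cohort(config: SyntheticCohortConfig) -> list[EEGRecording]:
    """All recordings of a cohort: one per subject, session and class.

    Per-subject jitter perturbs the band-power profiles multiplicatively
    (entrywise ``1 + eps``, ``eps ~ U(-subject_jitter, +subject_jitter)``,
    then re-normalized).  The same draw is applied to both class specs —
    jitter is a subject trait, not a class effect — so a null cohort stays
    exactly null.  Sessions of a subject share parameters and differ only
    in the noise realization.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    recordings: list[EEGRecording] = []
    for i, subj_ss in enumerate(subject_seeds):
        jitter_ss, *session_seeds = subj_ss.spawn(
            1 + config.n_sessions_per_subject
        )
        eps = np.random.default_rng(jitter_ss).uniform(
            -config.subject_jitter, config.subject_jitter,
            size=config.class_specs[0].band_power_profile.shape,
        )
        specs = [_jittered(s, eps) for s in config.class_specs]
        for j, sess_ss in enumerate(session_seeds):
            class_seeds = sess_ss.spawn(len(specs))
            for spec, class_ss in zip(specs, class_seeds):
                recordings.append(generate_recording(
                    spec, config.n_channels, config.sampling_rate,
                    config.duration_per_class, class_ss, scheme=config.scheme,
                    subject_id=f"S{i:02d}", session_id=str(j),
                ))
    return recordings


# ---------------------------------------------------------------------------
# Preset class-spec pairs: the four study conditions exercised in tests.

def _uniform_profile(n_channels: int, n_bands: int) -> np.ndarray:
    return np.full((n_channels, n_bands), 1.0 / n_bands)


def null_specs(n_channels: int = 6, n_bands: int = 8,
               noise_sd: float = 0.5) -> tuple[SyntheticClassSpec, SyntheticClassSpec]:
    """Identical classes: no detectable effect of any kind."""
    profile = _uniform_profile(n_channels, n_bands)
    loadings = np.zeros((n_channels, 1))
    return tuple(
        SyntheticClassSpec(profile.copy(), loadings.copy(), noise_sd, label)
        for label in (0, 1)
    )


def correlation_effect_specs(
    n_channels: int = 6, n_bands: int = 8, loading: float = 0.2,
    noise_sd: float = 0.6,
) -> tuple[SyntheticClassSpec, SyntheticClassSpec]:
    """Classes differ only in correlation structure.

    One shared factor; class 0 loads all channels with ``+loading``,
    class 1 flips the sign on the second half of the channels.  Sign flips
    leave every marginal spectrum unchanged, so band-power features carry
    no class information while half the channel pairs switch from positive
    to negative correlation.
    """
    profile = _uniform_profile(n_channels, n_bands)
    l0 = np.full((n_channels, 1), loading)
    l1 = l0.copy()
    l1[n_channels // 2:] *= -1.0
    return (
        SyntheticClassSpec(profile.copy(), l0, noise_sd, 0),
        SyntheticClassSpec(profile.copy(), l1, noise_sd, 1),
    )


def band_effect_specs(
    n_channels: int = 6, n_bands: int = 8, shift: float = 0.025,
    noise_sd: float = 0.5,
) -> tuple[SyntheticClassSpec, SyntheticClassSpec]:
    """Classes differ only in band-power profiles.

    Power ``shift`` is moved between the last two bands (equal 5 Hz widths
    in the default scheme, so correlation-noise statistics stay matched);
    channels are independent in both classes, leaving nothing for
    correlation graphs to detect.
    """
    if shift >= 1.0 / n_bands:
        raise ValueError("shift too large for a uniform base profile")
    p0 = _uniform_profile(n_channels, n_bands)
    p1 = p0.copy()
    p0[:, -2] += shift
    p0[:, -1] -= shift
    p1[:, -2] -= shift
    p1[:, -1] += shift
    loadings = np.zeros((n_channels, 1))
    return (
        SyntheticClassSpec(p0, loadings.copy(), noise_sd, 0),
        SyntheticClassSpec(p1, loadings.copy(), noise_sd, 1),
    )


def combined_effect_specs(
    n_channels: int = 6, n_bands: int = 8, loading: float = 0.2,
    shift: float = 0.025, noise_sd: float = 0.5,
) -> tuple[SyntheticClassSpec, SyntheticClassSpec]:
    """Both a correlation effect and a band-power effect."""
    c0, c1 = correlation_effect_specs(n_channels, n_bands, loading, noise_sd)
    b0, b1 = band_effect_specs(n_channels, n_bands, shift, noise_sd)
    return (
        SyntheticClassSpec(b0.band_power_profile, c0.latent_factor_loadings,
                           noise_sd, 0),
        SyntheticClassSpec(b1.band_power_profile, c1.latent_factor_loadings,
                           noise_sd, 1),
    )


def planted_channel_specs(
    n_channels: int = 5, n_bands: int = 8, channels: tuple[int, int] = (0, 1),
    loading: float = 0.9, shift: float = 0.08, noise_sd: float = 0.3,
) -> tuple[SyntheticClassSpec, SyntheticClassSpec]:
    """Class signal carried by two channels only (for ablation recovery).

    The planted pair correlates positively in class 0 and negatively in
    class 1, and additionally shifts band power between the last two bands;
    all remaining channels are identically distributed in both classes.
    """
    a, b = channels
    p0 = _uniform_profile(n_channels, n_bands)
    p1 = p0.copy()
    for ch in (a, b):
        p0[ch, -2] += shift
        p0[ch, -1] -= shift
        p1[ch, -2] -= shift
        p1[ch, -1] += shift
    l0 = np.zeros((n_channels, 1))
    l0[a, 0] = loading
    l0[b, 0] = loading
    l1 = l0.copy()
    l1[b, 0] = -loading
    return (
        SyntheticClassSpec(p0, l0, noise_sd, 0),
        SyntheticClassSpec(p1, l1, noise_sd, 1),
    )
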