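"""Synthetic EEG generator with planted, class-dependent band-power effects.

Emulates the trial structure of the two public emotion datasets this
package targets: a DEAP-like layout (32 channels at 128 Hz, 40 trials of
63 s with a 3 s pre-stimulus baseline, binary valence/arousal labels) and
a SEED-like layout (62 channels at 200 Hz, 15 trials of ~4 min, 3-class
labels).  The background of every channel is 1/f^a Gaussian noise plus a
low-amplitude oscillation in each of the five canonical frequency bands;
trials of the target class get the oscillation amplitude in one band, on a
designated set of channels, multiplied by ``effect_gain``.  Because the
planted effect is narrowband it is recoverable by any band-power estimate
(differential entropy included), which makes every downstream stage
testable without licensed recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import montage_channels

__all__ = [
    "BAND_EDGES",
    "SyntheticConfig",
    "RawRecording",
    "deap_like_config",
    "seed_like_config",
    "generate_recording",
    "split_baseline",
]

#: Canonical EEG rhythm bands (Hz), fixed order used throughout the package.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 31.0),
    "gamma": (31.0, 50.0),
}


class ConfigurationError(ValueError):
    """Invalid generator / pipeline configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic EEG study.

    Amplitudes are in arbitrary units on a 1/f^a background of unit-scale
    standard deviation; the absolute scale is irrelevant to the pipeline
    (differential entropy shifts by a constant under global rescaling).
    """

    n_subjects: int = 1
    n_trials: int = 40
    n_channels: int = 32
    fs: float = 128.0
    trial_len_s: float = 63.0
    baseline_len_s: float = 3.0
    n_classes: int = 2
    effect_channels: tuple[str, ...] = ("Fp1", "Fp2", "AF3", "AF4")
    effect_band: str = "alpha"
    effect_gain: float = 3.0
    noise_exponent: float = 1.0
    osc_amplitude: float = 0.3
    seed: int = 0
    channel_names: tuple[str, ...] | None = None

    def resolved_channels(self) -> tuple[str, ...]:
        if self.channel_names is not None:
            return tuple(self.channel_names)
        return tuple(montage_channels(self.n_channels))

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        hi = max(b for _, b in BAND_EDGES.values())
        if self.fs < 2 * hi:
            raise ConfigurationError(
                f"fs={self.fs} Hz cannot represent the {hi} Hz upper band edge"
            )
        if self.effect_band not in BAND_EDGES:
            raise ConfigurationError(f"unknown band {self.effect_band!r}")
        if self.effect_gain < 1:
            raise ConfigurationError("effect_gain must be >= 1")
        names = self.resolved_channels()
        for ch in self.effect_channels:
            if ch not in names:
                raise ConfigurationError(f"effect channel {ch!r} not in montage")
        n_samp = self.trial_len_s * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ConfigurationError("trial_len_s * fs must be an integer")


@dataclass
class RawRecording:
    """Continuous multichannel EEG cut into trials.

    data has shape (trials, channels, samples); the first
    ``baseline_samples`` samples of every trial are pre-stimulus.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    labels: np.ndarray
    baseline_samples: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal channel axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def deap_like_config(**overrides) -> SyntheticConfig:
    """32 channels, 128 Hz, 40 x 63 s trials with a 3 s baseline, 2 classes."""
    return replace(SyntheticConfig(), **overrides)


def seed_like_config(**overrides) -> SyntheticConfig:
    """62 channels, 200 Hz, 15 trials of 235 s, no baseline, 3 classes."""
    base = SyntheticConfig(
        n_trials=15,
        n_channels=62,
        fs=200.0,
        trial_len_s=235.0,
        baseline_len_s=0.0,
        n_classes=3,
        effect_channels=("T7", "T8", "TP7", "TP8"),
    )
    return replace(base, **overrides)


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to ~1/f^exponent, unit std."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _band_oscillation(
    rng: np.random.Generator, t: np.ndarray, low: float, high: float
) -> np.ndarray:
    """Random-phase sinusoid at a frequency drawn uniformly inside the band."""
    f = rng.uniform(low, high)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return np.sin(2.0 * np.pi * f * t + phase)


def generate_recording(cfg: SyntheticConfig, subject_index: int = 0) -> RawRecording:
    """Generate one subject's recording; a pure function of (cfg, subject_index).

    Each subject draws from an independent stream spawned from
    (cfg.seed, subject_index), so subjects are individually reproducible.
    """
    cfg.validate()
    names = list(cfg.resolved_channels())
    n_samp = int(round(cfg.trial_len_s * cfg.fs))
    t = np.arange(n_samp) / cfg.fs
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index)))

    labels = rng.integers(0, cfg.n_classes, size=cfg.n_trials)
    # ensure every class occurs (tiny trial counts would otherwise degenerate)
    for c in range(cfg.n_classes):
        if not np.any(labels == c):
            labels[rng.integers(0, cfg.n_trials)] = c

    target_class = cfg.n_classes - 1
    effect_idx = {names.index(ch) for ch in cfg.effect_channels}

    data = np.empty((cfg.n_trials, len(names), n_samp))
    for trial in range(cfg.n_trials):
        boosted = labels[trial] == target_class
        for ci in range(len(names)):
            x = _one_over_f_noise(rng, n_samp, cfg.noise_exponent)
            for band, (lo, hi) in BAND_EDGES.items():
                amp = cfg.osc_amplitude
                if boosted and band == cfg.effect_band and ci in effect_idx:
                    amp *= cfg.effect_gain
                x = x + amp * _band_oscillation(rng, t, lo, hi)
            data[trial, ci] = x

    return RawRecording(
        subject_id=f"S{subject_index:02d}",
        data=data,
        fs=cfg.fs,
        channel_names=names,
        labels=labels,
        baseline_samples=int(round(cfg.baseline_len_s * cfg.fs)),
    )


def split_baseline(rec: RawRecording) -> RawRecording:
    """Drop the leading pre-stimulus samples from every trial.

    Labels are untouched; the returned recording has baseline_samples = 0.
    """
    nb = rec.baseline_samples
    if nb > rec.n_samples:
        raise IndexError(
            f"baseline of {nb} samples exceeds trial length {rec.n_samples}"
        )
    if nb == 0:
        return rec
    return RawRecording(
        subject_id=rec.subject_id,
        data=rec.data[:, :, nb:].copy(),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        labels=rec.labels.copy(),
        baseline_samples=0,
    )
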