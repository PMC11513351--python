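"""Band decomposition, segmentation and differential-entropy features.

The pipeline is: (1) decompose each channel into the five canonical EEG
rhythm bands with a third-order Butterworth bandpass (zero-phase by
default); (2) cut each trial non-overlappingly into windows of T seconds
and each window into 1-s patches; (3) for every patch, band and channel
compute the differential entropy (DE) of the band-limited signal.  A
band-limited EEG patch is well approximated as Gaussian, for which the
differential entropy has the closed form

    DE = 1/2 * ln(2 * pi * e * sigma^2)   [nats]

so the feature reduces to a log-variance.  The result is a PatchTensor of
shape (windows n, patches-per-window T, bands B=5, channels C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic import BAND_EDGES, ConfigurationError, RawRecording

__all__ = [
    "FilterBank",
    "SegmentationPlan",
    "PatchTensor",
    "DegenerateInputError",
    "bandpass_decompose",
    "segment",
    "de_feature",
    "build_patch_tensor",
    "threshold_ratings",
]


class DegenerateInputError(ValueError):
    """Input that makes a feature undefined (e.g. zero-variance patch)."""


@dataclass(frozen=True)
class FilterBank:
    """Third-order Butterworth bandpass bank over the five EEG bands.

    zero_phase applies the filter forward and backward (no phase
    distortion, effective order doubled); set False for causal filtering.
    """

    bands: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in BAND_EDGES.items()
    )
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ConfigurationError(f"band {name}: edges must satisfy 0 < lo < hi")

    @property
    def band_names(self) -> list[str]:
        return [name for name, _, _ in self.bands]

    @property
    def max_edge(self) -> float:
        return max(hi for _, _, hi in self.bands)


@dataclass(frozen=True)
class SegmentationPlan:
    """Non-overlapping T-second windows of 1-s patches; remainder discarded."""

    window_len_s: int = 8
    patch_len_s: int = 1

    def __post_init__(self) -> None:
        if self.window_len_s % self.patch_len_s != 0:
            raise ConfigurationError("window length must be a multiple of patch length")

    @property
    def patches_per_window(self) -> int:
        return self.window_len_s // self.patch_len_s


@dataclass
class PatchTensor:
    """DE features in nats, shape (n windows, T patches, B bands, C channels).

    window_trials records each window's source trial so cross-validation
    can split at trial granularity without within-trial leakage.
    """

    values: np.ndarray
    band_names: list[str]
    channel_names: list[str]
    window_labels: np.ndarray
    subject_id: str = ""
    window_trials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("values must be (n, T, B, C)")
        if self.values.shape[2] != len(self.band_names):
            raise ValueError("band axis does not match band_names")
        if self.values.shape[3] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if len(self.window_labels) != self.values.shape[0]:
            raise ValueError("window_labels must have one entry per window")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite DE values")


def bandpass_decompose(rec: RawRecording, fb: FilterBank | None = None) -> np.ndarray:
    """Filter every channel into each band.

    Returns an array of shape (trials, bands, channels, samples); output
    length equals input length in every band.
    """
    fb = fb or FilterBank()
    if rec.fs < 2 * fb.max_edge:
        raise ConfigurationError(
            f"fs={rec.fs} Hz below Nyquist requirement for {fb.max_edge} Hz band edge"
        )
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("NaN or infinite samples in recording")

    trials, channels, samples = rec.data.shape
    out = np.empty((trials, len(fb.bands), channels, samples))
    for bi, (_, lo, hi) in enumerate(fb.bands):
        sos = signal.butter(fb.order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
        if fb.zero_phase:
            out[:, bi] = signal.sosfiltfilt(sos, rec.data, axis=-1)
        else:
            out[:, bi] = signal.sosfilt(sos, rec.data, axis=-1)
    return out


def segment(
    banded: np.ndarray, fs: float, plan: SegmentationPlan
) -> np.ndarray:
    """Cut (trials, bands, channels, samples) into windows of 1-s patches.

    Returns (trials, windows-per-trial, T, bands, channels, patch_samples);
    the trailing remainder shorter than one window is discarded.
    """
    trials, bands, channels, samples = banded.shape
    win_samp = int(round(plan.window_len_s * fs))
    patch_samp = int(round(plan.patch_len_s * fs))
    n_windows = samples // win_samp
    if n_windows < 1:
        raise ValueError(
            f"trial of {samples} samples shorter than one {plan.window_len_s} s window"
        )
    T = plan.patches_per_window
    usable = banded[..., : n_windows * win_samp]
    # (trials, bands, channels, n, T, patch) -> (trials, n, T, bands, channels, patch)
    shaped = usable.reshape(trials, bands, channels, n_windows, T, patch_samp)
    return np.transpose(shaped, (0, 3, 4, 1, 2, 5))


def de_feature(patch: np.ndarray, ddof: int = 0) -> float | np.ndarray:
    """Differential entropy 1/2 ln(2 pi e sigma^2) of the trailing axis, in nats.

    sigma^2 is the population variance by default (ddof=0), treating the
    variance as the Gaussian distribution parameter; ddof=1 selects the
    unbiased estimator.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape[-1] < 2:
        raise DegenerateInputError("patch needs at least 2 samples")
    var = patch.var(axis=-1, ddof=ddof)
    if np.any(var <= 0):
        raise DegenerateInputError("zero-variance patch: differential entropy undefined")
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def build_patch_tensor(
    rec: RawRecording,
    fb: FilterBank | None = None,
    plan: SegmentationPlan | None = None,
    baseline: str = "drop",
    ddof: int = 0,
) -> PatchTensor:
    """Full feature path: baseline handling, filterbank, segmentation, DE.

    baseline: 'drop' removes the pre-stimulus samples (default), 'none'
    keeps them. Windows inherit their source trial's label.
    """
    from .synthetic import split_baseline

    fb = fb or FilterBank()
    plan = plan or SegmentationPlan()
    if baseline == "drop":
        rec = split_baseline(rec)
    elif baseline != "none":
        raise ConfigurationError(f"unknown baseline policy {baseline!r}")

    banded = bandpass_decompose(rec, fb)
    patches = segment(banded, rec.fs, plan)  # (trials, nw, T, B, C, ps)
    de = de_feature(patches, ddof=ddof)  # (trials, nw, T, B, C)
    trials, nw, T, B, C = de.shape
    values = de.reshape(trials * nw, T, B, C)
    window_labels = np.repeat(np.asarray(rec.labels), nw)
    window_trials = np.repeat(np.arange(trials), nw)
    return PatchTensor(
        values=values,
        band_names=fb.band_names,
        channel_names=list(rec.channel_names),
        window_labels=window_labels,
        subject_id=rec.subject_id,
        window_trials=window_trials,
    )


def threshold_ratings(ratings: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Binarize continuous 1-9 affect ratings: high (1) iff rating > threshold."""
    return (np.asarray(ratings, dtype=float) > threshold).astype(np.int64)
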