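"""Filterbank, segmentation and differential-entropy features."""

import numpy as np
import pytest

import hastf
from hastf.preprocess import (
    DegenerateInputError,
    FilterBank,
    SegmentationPlan,
    bandpass_decompose,
    de_feature,
    segment,
    threshold_ratings,
)
from hastf.synthetic import ConfigurationError, RawRecording

DE_UNIT_VARIANCE = 0.5 * np.log(2 * np.pi * np.e)  # ~1.41894 nats


def fft_band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Independent periodogram band-power oracle."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return float(spec[(freqs >= lo) & (freqs <= hi)].sum())


def _recording_from_array(data: np.ndarray, fs: float) -> RawRecording:
    trials, channels, _ = data.shape
    return RawRecording(
        subject_id="T",
        data=data,
        fs=fs,
        channel_names=[f"ch{i}" for i in range(channels)],
        labels=np.zeros(trials, dtype=int),
    )


def test_pure_alpha_tone_lands_in_alpha_band():
    fs = 128.0
    t = np.arange(int(fs * 8)) / fs
    tone = np.sin(2 * np.pi * 10.0 * t)
    rec = _recording_from_array(tone[None, None, :], fs)
    banded = bandpass_decompose(rec)  # (1, 5, 1, samples)
    total = fft_band_power(tone, fs, 0, fs / 2)
    alpha_out = fft_band_power(banded[0, 2, 0], fs, 0, fs / 2)
    delta_out = fft_band_power(banded[0, 0, 0], fs, 0, fs / 2)
    assert alpha_out >= 0.9 * total
    assert delta_out <= 0.01 * total


def test_zero_input_gives_zero_output_in_every_band():
    rec = _recording_from_array(np.zeros((1, 2, 512)), 128.0)
    banded = bandpass_decompose(rec)
    assert np.allclose(banded, 0.0)


def test_low_sampling_rate_rejected_for_gamma():
    rec = _recording_from_array(np.random.default_rng(0).standard_normal((1, 1, 400)), 80.0)
    with pytest.raises(ConfigurationError):
        bandpass_decompose(rec)


def test_nan_input_rejected():
    data = np.zeros((1, 1, 256))
    rec = _recording_from_array(data, 128.0)
    rec.data[0, 0, 5] = np.nan  # bypass constructor check deliberately
    with pytest.raises(ValueError):
        bandpass_decompose(rec)


def test_filterbank_band_powers_bounded_by_total():
    """For white noise the per-band powers sum to at most the input power."""
    rng = np.random.default_rng(8)
    x = rng.standard_normal((1, 1, 4096))
    rec = _recording_from_array(x, 128.0)
    banded = bandpass_decompose(rec)
    band_sum = sum(banded[0, b, 0].var() for b in range(5))
    assert band_sum <= 1.05 * x.var()


class TestDifferentialEntropy:
    def test_closed_form_at_unit_variance(self):
        patch = np.tile([-1.0, 1.0], 64)  # population variance exactly 1
        assert de_feature(patch) == pytest.approx(DE_UNIT_VARIANCE, abs=1e-12)

    def test_amplitude_doubling_adds_ln2(self):
        rng = np.random.default_rng(1)
        patch = rng.standard_normal(128)
        assert de_feature(2 * patch) - de_feature(patch) == pytest.approx(np.log(2), abs=1e-12)

    def test_gaussian_draws_match_direct_formula(self):
        rng = np.random.default_rng(2)
        patch = rng.standard_normal(128)
        direct = 0.5 * np.log(2 * np.pi * np.e * patch.var())  # same estimator, by hand
        assert de_feature(patch) == pytest.approx(direct, abs=1e-12)
        assert abs(de_feature(patch) - DE_UNIT_VARIANCE) < 0.2

    def test_unbiased_estimator_option(self):
        patch = np.array([0.0, 1.0, 2.0, 3.0])
        expect = 0.5 * np.log(2 * np.pi * np.e * patch.var(ddof=1))
        assert de_feature(patch, ddof=1) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_patches_raise(self):
        with pytest.raises(DegenerateInputError):
            de_feature(np.zeros(16))
        with pytest.raises(DegenerateInputError):
            de_feature(np.array([1.0]))


class TestSegmentation:
    def test_deap_like_window_count(self):
        banded = np.zeros((1, 5, 2, 60 * 128))
        out = segment(banded, 128.0, SegmentationPlan(window_len_s=8))
        assert out.shape == (1, 7, 8, 5, 2, 128)  # floor(60/8)=7 windows, 4 s dropped

    def test_seed_like_patch_count(self):
        banded = np.zeros((1, 5, 2, 11 * 200))
        out = segment(banded, 200.0, SegmentationPlan(window_len_s=11))
        assert out.shape[1:3] == (1, 11)

    def test_too_short_trial_raises(self):
        banded = np.zeros((1, 5, 2, 7 * 128))
        with pytest.raises(ValueError):
            segment(banded, 128.0, SegmentationPlan(window_len_s=8))

    def test_patch_conservation_and_no_overlap(self):
        """Segmented patches tile the retained samples exactly."""
        rng = np.random.default_rng(3)
        banded = rng.standard_normal((2, 5, 3, 20 * 64))
        out = segment(banded, 64.0, SegmentationPlan(window_len_s=8))
        n_windows = out.shape[1]
        assert n_windows == 20 // 8
        recon = np.transpose(out, (0, 3, 4, 1, 2, 5)).reshape(2, 5, 3, -1)
        np.testing.assert_array_equal(recon, banded[..., : n_windows * 8 * 64])


def test_build_patch_tensor_shapes_and_labels(tiny_recording, tiny_patch_tensor):
    pt = tiny_patch_tensor
    usable = 16  # 19 s - 3 s baseline
    per_trial = usable // 8
    assert pt.values.shape == (6 * per_trial, 8, 5, 32)
    expect_labels = np.repeat(tiny_recording.labels, per_trial)
    np.testing.assert_array_equal(pt.window_labels, expect_labels)
    np.testing.assert_array_equal(pt.window_trials, np.repeat(np.arange(6), per_trial))


def test_planted_effect_raises_alpha_de_on_effect_channels(tiny_patch_tensor, tiny_recording):
    """Target-class windows carry higher alpha DE on the planted channels."""
    pt = tiny_patch_tensor
    alpha = pt.band_names.index("alpha")
    idx = [pt.channel_names.index(ch) for ch in ("Fp1", "Fp2", "AF3", "AF4")]
    de = pt.values[:, :, alpha][:, :, idx].mean(axis=(1, 2))
    target = pt.window_labels == 1
    assert de[target].mean() > de[~target].mean()


def test_rating_threshold_binarization():
    ratings = np.array([1.0, 4.9, 5.0, 5.1, 9.0])
    np.testing.assert_array_equal(threshold_ratings(ratings), [0, 0, 0, 1, 1])
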