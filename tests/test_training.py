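"""Cross-validation folds, metrics, and small-scale training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hastf
from hastf.montage import load_montage, map_to_grid
from hastf.network import HASTFConfig, desk_scale_config
from hastf.preprocess import PatchTensor
from hastf.safe import UCCFConfig
from hastf.tafe import EncoderConfig
from hastf.training import (
    TrainConfig,
    accuracy,
    make_folds,
    pop_std,
    run_ablation,
    train_subject,
)


class TestFolds:
    @pytest.mark.parametrize("units,size", [(40, 8), (15, 3)])
    def test_equal_fold_sizes(self, units, size):
        folds = make_folds(units, k=5, seed=0)
        assert all(len(f.test_idx) == size for f in folds)

    @given(units=st.integers(5, 97), seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_folds_partition_units(self, units, seed):
        folds = make_folds(units, k=5, seed=seed)
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test) == list(range(units))
        sizes = [len(f.test_idx) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        for f in folds:
            assert set(f.train_idx).isdisjoint(f.test_idx)
            assert len(f.train_idx) + len(f.test_idx) == units

    def test_seeded_determinism(self):
        a = make_folds(23, seed=5)
        b = make_folds(23, seed=5)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test_idx, fb.test_idx)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            make_folds(4, k=5)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expect", [((3, 4, 2, 1), 70.0), ((5, 5, 0, 0), 100.0), ((0, 0, 5, 5), 0.0)]
    )
    def test_accuracy_from_confusion_counts(self, counts, expect):
        assert accuracy(*counts) == pytest.approx(expect)

    def test_accuracy_zero_total_undefined(self):
        with pytest.raises(ZeroDivisionError):
            accuracy(0, 0, 0, 0)

    @pytest.mark.parametrize(
        "values,expect", [([2, 4], 1.0), ([3, 3, 3], 0.0), ([1, 2, 3, 4], 1.1180)]
    )
    def test_population_std(self, values, expect):
        assert pop_std(values) == pytest.approx(expect, abs=1e-4)

    def test_std_empty_undefined(self):
        with pytest.raises(ValueError):
            pop_std([])


def _toy_grids(n_trials=10, windows_per_trial=2, T=4, seed=0, separation=3.0):
    """Directly constructed DE-like grids with a class offset on 4 channels."""
    mg = load_montage("deap32")
    rng = np.random.default_rng(seed)
    n = n_trials * windows_per_trial
    labels_trial = np.tile([0, 1], n_trials // 2 + 1)[:n_trials]
    values = rng.standard_normal((n, T, 5, 32)) * 0.3
    labels = np.repeat(labels_trial, windows_per_trial)
    idx = [mg.channel_names.index(c) for c in ("Fp1", "Fp2", "AF3", "AF4")]
    values[labels == 1][..., :] += 0.0  # no-op to keep shape obvious
    for ci in idx:
        values[labels == 1, :, 2, ci] += separation
    pt = PatchTensor(
        values=values,
        band_names=["delta", "theta", "alpha", "beta", "gamma"],
        channel_names=mg.channel_names,
        window_labels=labels,
        window_trials=np.repeat(np.arange(n_trials), windows_per_trial),
        subject_id="toy",
    )
    return map_to_grid(pt, mg)


TINY_MODEL = HASTFConfig(
    uccf=UCCFConfig(filters=(4, 8, 8, 4, 4)),
    encoder=EncoderConfig(n_layers=1, n_heads=2, model_dim=16, qkv_dim=16, ffn_dim=8),
    embed_dim=16,
)


class TestTrainSubject:
    def test_same_seed_is_bit_reproducible(self):
        grids = _toy_grids()
        cfg = TrainConfig(lr=1e-3, epochs=2, seed=9)
        a = train_subject(grids, TINY_MODEL, cfg)
        b = train_subject(grids, TINY_MODEL, cfg)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.fold_losses == b.fold_losses
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_separable_data_learned(self):
        grids = _toy_grids(n_trials=20, separation=3.0)
        cfg = TrainConfig(lr=1e-2, epochs=8, seed=1)
        res = train_subject(grids, TINY_MODEL, cfg)
        assert res.mean_accuracy >= 85.0

    def test_training_loss_decreases_smoothed(self):
        grids = _toy_grids(n_trials=20, separation=3.0)
        cfg = TrainConfig(lr=1e-2, epochs=10, seed=2)
        res = train_subject(grids, TINY_MODEL, cfg)
        losses = np.array(res.fold_losses[0])
        k = 5
        smooth = np.convolve(losses, np.ones(k) / k, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_single_class_fold_rejected(self):
        grids = _toy_grids(n_trials=10)
        grids.window_labels[:] = 0
        grids.window_labels[-2:] = 1
        with pytest.raises(ValueError, match="single class"):
            train_subject(grids, TINY_MODEL, TrainConfig(epochs=1, seed=0))

    def test_window_split_mode_runs(self):
        grids = _toy_grids(n_trials=10)
        res = train_subject(
            grids, TINY_MODEL, TrainConfig(lr=1e-2, epochs=1, seed=0, split_unit="window")
        )
        assert len(res.fold_accuracies) == 5

    def test_confusion_counts_total_windows(self):
        grids = _toy_grids(n_trials=10)
        res = train_subject(grids, TINY_MODEL, TrainConfig(epochs=1, seed=0))
        assert res.confusion.sum() == grids.values.shape[0]


class TestAblation:
    def test_report_shape_and_paired_folds(self):
        grids = _toy_grids(n_trials=10)
        report = run_ablation(
            grids,
            variants=("All", "Wo-SA"),
            model_cfg=TINY_MODEL,
            train_cfg=TrainConfig(lr=1e-2, epochs=1, seed=3),
        )
        assert set(report.results) == {"All", "Wo-SA"}
        assert all(len(r.fold_accuracies) == 5 for r in report.results.values())
        df = report.to_frame()
        assert len(df) == 10
        assert set(df.columns) >= {"variant", "fold", "accuracy"}

    def test_anova_and_posthoc_run_on_report(self):
        grids = _toy_grids(n_trials=10)
        report = run_ablation(
            grids,
            variants=("All", "Wo-SAFE", "Wo-TAFE"),
            model_cfg=TINY_MODEL,
            train_cfg=TrainConfig(lr=1e-2, epochs=2, seed=4),
        )
        anova = report.anova()
        assert anova.df_between == 2
        assert anova.df_within == 12
        pairs = report.posthoc()
        assert len(pairs) == 3


def test_model_results_facade():
    model = hastf.HASTF(_toy_grids(n_trials=10), config=TINY_MODEL)
    res = model.fit(TrainConfig(lr=1e-2, epochs=2, seed=0))
    assert 0.0 <= res.mean_accuracy <= 100.0
    text = res.summary()
    assert "mean accuracy" in text and "fold 5" in text
    assert res.to_frame().shape == (5, 2)


def test_model_from_recording_builds_grids(tiny_recording):
    model = hastf.HASTF.from_recording(tiny_recording)
    n, T, B, h, w = model.grids.values.shape
    assert (T, B, h, w) == (8, 5, 9, 9)
    assert model.grids.montage.name == "deap32"
    assert model.config.n_classes == 2
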