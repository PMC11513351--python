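"""Model/Results interface over the full pipeline.

``HASTF`` is constructed from a subject's data (a :class:`GridTensor`,
or directly from a :class:`RawRecording` via :meth:`HASTF.from_recording`)
plus an architecture configuration; ``fit()`` runs subject-dependent
5-fold cross-validation and returns a :class:`HASTFResults` carrying the
per-fold accuracies, their mean and population spread, the confusion
counts and the training curves, with a ``summary()`` table.
``fit_ablation()`` trains the structural variants on identical folds and
returns an :class:`AblationReport` (which exposes ``anova()`` and
``posthoc()``).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .montage import GridTensor, load_montage, map_to_grid
from .network import HASTFConfig, desk_scale_config, reference_scale_config
from .preprocess import FilterBank, SegmentationPlan, build_patch_tensor
from .synthetic import RawRecording
from .training import (
    AblationReport,
    EvalResult,
    TrainConfig,
    run_ablation,
    train_subject,
)

__all__ = ["HASTF", "HASTFResults"]


class HASTF:
    """Hybrid attention spatio-temporal emotion classifier for one subject."""

    def __init__(
        self,
        grids: GridTensor,
        config: HASTFConfig | None = None,
        variant: str = "All",
    ):
        self.grids = grids
        T = grids.values.shape[1]
        n_classes = len(np.unique(np.asarray(grids.window_labels)))
        if config is None:
            config = desk_scale_config(seq_len_t=T, n_classes=n_classes)
        else:
            config = replace(config, seq_len_t=T, n_classes=n_classes)
        self.config = config
        self.variant = variant

    @classmethod
    def from_recording(
        cls,
        rec: RawRecording,
        montage: str = None,
        window_len_s: int | None = None,
        config: HASTFConfig | None = None,
        baseline: str = "drop",
        **kwargs,
    ) -> "HASTF":
        """Build the model straight from a raw recording: filterbank ->
        segmentation -> DE -> 9x9 grid mapping."""
        if montage is None:
            montage = "deap32" if len(rec.channel_names) == 32 else "seed62"
        if window_len_s is None:
            window_len_s = 8 if len(rec.channel_names) == 32 else 11
        pt = build_patch_tensor(
            rec,
            FilterBank(),
            SegmentationPlan(window_len_s=window_len_s),
            baseline=baseline,
        )
        grids = map_to_grid(pt, load_montage(montage))
        return cls(grids, config=config, **kwargs)

    def fit(self, train_config: TrainConfig | None = None) -> "HASTFResults":
        result = train_subject(
            self.grids, self.config, train_config, variant=self.variant
        )
        return HASTFResults(self, result, train_config or TrainConfig())

    def fit_ablation(
        self,
        variants: tuple[str, ...] = ("All", "Wo-Sc", "Wo-SA", "Wo-UCCF", "Wo-SAFE"),
        train_config: TrainConfig | None = None,
    ) -> AblationReport:
        return run_ablation(self.grids, variants, self.config, train_config)


class HASTFResults:
    """Cross-validation results of a fitted :class:`HASTF` model."""

    def __init__(self, model: HASTF, result: EvalResult, train_config: TrainConfig):
        self.model = model
        self.result = result
        self.train_config = train_config

    @property
    def fold_accuracies(self) -> list[float]:
        return self.result.fold_accuracies

    @property
    def mean_accuracy(self) -> float:
        return self.result.mean_accuracy

    @property
    def std_accuracy(self) -> float:
        return self.result.std_accuracy

    @property
    def confusion(self) -> np.ndarray:
        return self.result.confusion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(1, len(self.fold_accuracies) + 1),
                "accuracy": self.fold_accuracies,
            }
        )

    def summary(self) -> str:
        res, cfg = self.result, self.model.config
        lines = [
            "HASTF cross-validation results",
            "=" * 46,
            f"subject:            {self.model.grids.subject_id or '<unnamed>'}",
            f"variant:            {res.variant}",
            f"montage:            {self.model.grids.montage.name}",
            f"windows:            {self.model.grids.values.shape[0]}"
            f"  (T={cfg.seq_len_t} patches)",
            f"classes:            {cfg.n_classes}",
            f"split unit:         {self.train_config.split_unit}",
            f"epochs / lr:        {self.train_config.epochs} / {self.train_config.lr}",
            "-" * 46,
        ]
        for i, acc in enumerate(res.fold_accuracies, start=1):
            lines.append(f"fold {i} accuracy:    {acc:6.2f} %")
        lines += [
            "-" * 46,
            f"mean accuracy:      {res.mean_accuracy:6.2f} %",
            f"population std:     {res.std_accuracy:6.2f} %",
            "=" * 46,
        ]
        return "\n".join(lines)
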