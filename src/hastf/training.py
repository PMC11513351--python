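"""Subject-dependent 5-fold cross-validation training and ablations.

One model is trained per subject (and per session for SEED-style data).
Units — trials by default, windows optionally — are shuffled with a
seeded generator and partitioned into five near-equal folds; each fold
serves once as the test set.  Splitting at trial granularity keeps all
windows of a trial in one fold and so avoids within-trial leakage; the
``window`` mode matches the looser reading of shuffling all samples and
typically inflates accuracy (use with care).

Metrics: accuracy = 100 (TP+TN) / (TP+FP+TN+FN); the spread over folds is
the population standard deviation (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import GridTensor
from .network import HASTFConfig, HASTFNetwork, cross_entropy, desk_scale_config
from .nn import AdamW, Tensor

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "EvalResult",
    "AblationReport",
    "desk_scale_train_config",
    "make_folds",
    "accuracy",
    "pop_std",
    "train_subject",
    "run_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the reference protocol
    (cross-entropy, AdamW, lr 1e-4, weight decay 1e-4, batch 32,
    100 epochs)."""

    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    split_unit: str = "trial"
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.split_unit not in ("trial", "window"):
            raise ValueError(f"unknown split_unit {self.split_unit!r}")


def desk_scale_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Reduced protocol for CPU-scale runs: 20 epochs at lr 1e-3."""
    return replace(TrainConfig(lr=1e-3, epochs=20, seed=seed), **overrides)


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def make_folds(units: int, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Seeded shuffle, then contiguous partition into k near-equal folds.

    The folds partition range(units); each unit is in exactly one test
    set and fold sizes differ by at most one.
    """
    if units < k:
        raise ValueError(f"cannot make {k} folds from {units} units")
    rng = np.random.default_rng(seed)
    order = rng.permutation(units)
    chunks = np.array_split(order, k)
    folds = []
    for i, test in enumerate(chunks):
        train = np.concatenate([c for j, c in enumerate(chunks) if j != i])
        folds.append(FoldSplit(fold_id=i + 1, train_idx=np.sort(train), test_idx=np.sort(test)))
    return folds


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Classification accuracy in percent from confusion counts."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ZeroDivisionError("accuracy undefined for zero total count")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return 100.0 * (tp + tn) / total


def pop_std(values) -> float:
    """Population standard deviation (divide by N)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("std undefined for empty input")
    return float(np.sqrt(np.mean((arr - arr.mean()) ** 2)))


@dataclass
class EvalResult:
    """Cross-validated performance of one variant on one subject."""

    variant: str
    fold_accuracies: list[float]  # percent, one per fold
    confusion: np.ndarray  # (n_classes, n_classes), rows = true
    fold_losses: list[list[float]] = field(default_factory=list)
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return pop_std(self.fold_accuracies)


def _predict(net: HASTFNetwork, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    preds = []
    for lo in range(0, x.shape[0], chunk):
        logits = net(Tensor(x[lo : lo + chunk]))
        preds.append(logits.data.argmax(axis=1))
    return np.concatenate(preds)


def _train_one(
    net: HASTFNetwork,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> list[float]:
    opt = AdamW(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            loss = cross_entropy(net(Tensor(x[idx])), y[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / len(y))
    return losses


def _fold_window_indices(
    folds: list[FoldSplit], unit_of_window: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for f in folds:
        tr = np.flatnonzero(np.isin(unit_of_window, f.train_idx))
        te = np.flatnonzero(np.isin(unit_of_window, f.test_idx))
        out.append((tr, te))
    return out


def train_subject(
    grids: GridTensor,
    model_cfg: HASTFConfig | None = None,
    train_cfg: TrainConfig | None = None,
    variant: str = "All",
    folds: list[FoldSplit] | None = None,
) -> EvalResult:
    """Train and evaluate one subject with k-fold cross-validation.

    Every fold gets a freshly initialized network seeded from
    (train_cfg.seed, fold_id), so repeated invocations are bit-identical.
    """
    y_all = np.asarray(grids.window_labels)
    classes = np.unique(y_all)
    remap = {c: i for i, c in enumerate(classes)}
    y = np.array([remap[c] for c in y_all])
    n_classes = len(classes)
    T = grids.values.shape[1]

    train_cfg = train_cfg or TrainConfig()
    if model_cfg is None:
        model_cfg = desk_scale_config(seq_len_t=T, n_classes=n_classes)
    if model_cfg.seq_len_t != T or model_cfg.n_classes != n_classes:
        model_cfg = replace(model_cfg, seq_len_t=T, n_classes=n_classes)

    if train_cfg.split_unit == "trial":
        if grids.window_trials is None:
            raise ValueError("trial-level split requires window_trials on the grids")
        unit_of_window = np.asarray(grids.window_trials)
        n_units = len(np.unique(unit_of_window))
    else:
        unit_of_window = np.arange(len(y))
        n_units = len(y)

    if folds is None:
        folds = make_folds(n_units, k=train_cfg.n_folds, seed=train_cfg.seed)
    window_folds = _fold_window_indices(folds, unit_of_window)

    x = grids.values
    fold_accs: list[float] = []
    fold_losses: list[list[float]] = []
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for f, (tr, te) in zip(folds, window_folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f.fold_id}: training set contains a single class")
        rng = np.random.default_rng(np.random.SeedSequence((train_cfg.seed, f.fold_id)))
        net = HASTFNetwork(model_cfg, rng, variant=variant)
        losses = _train_one(net, x[tr], y[tr], train_cfg, rng)
        pred = _predict(net, x[te])
        correct = int((pred == y[te]).sum())
        fold_accs.append(100.0 * correct / len(te))
        fold_losses.append(losses)
        for yt, yp in zip(y[te], pred):
            confusion[yt, yp] += 1

    return EvalResult(
        variant=variant,
        fold_accuracies=fold_accs,
        confusion=confusion,
        fold_losses=fold_losses,
        seed=train_cfg.seed,
    )


@dataclass
class AblationReport:
    """Per-variant cross-validated accuracies plus the fold design.

    ``anova()`` tests equality of the variant means (one-way, on per-fold
    accuracies); ``posthoc()`` runs Games-Howell pairwise comparisons.
    """

    results: dict[str, EvalResult]
    folds: list[FoldSplit]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            for fold, acc in enumerate(res.fold_accuracies, start=1):
                rows.append({"variant": name, "fold": fold, "accuracy": acc, "seed": res.seed})
        return pd.DataFrame(rows)

    def accuracy_groups(self) -> dict[str, list[float]]:
        return {name: list(res.fold_accuracies) for name, res in self.results.items()}

    def anova(self):
        from .stats import one_way_anova

        return one_way_anova(list(self.accuracy_groups().values()))

    def posthoc(self):
        from .stats import games_howell

        groups = self.accuracy_groups()
        return games_howell(list(groups.values()), names=list(groups))


def run_ablation(
    grids: GridTensor,
    variants: tuple[str, ...] = ("All", "Wo-Sc", "Wo-SA", "Wo-UCCF", "Wo-SAFE"),
    model_cfg: HASTFConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> AblationReport:
    """Train every variant on identical folds and seeds (paired design)."""
    train_cfg = train_cfg or TrainConfig()
    y = np.asarray(grids.window_labels)
    if train_cfg.split_unit == "trial":
        n_units = len(np.unique(np.asarray(grids.window_trials)))
    else:
        n_units = len(y)
    folds = make_folds(n_units, k=train_cfg.n_folds, seed=train_cfg.seed)
    results = {
        v: train_subject(grids, model_cfg, train_cfg, variant=v, folds=folds)
        for v in variants
    }
    return AblationReport(results=results, folds=folds)
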