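"""Training protocol and stratified K-fold cross-validated scoring.

Models train with Adam (learning rate 0.001) on categorical cross-entropy,
with per-task batch sizes, early stopping (patience 20, best-loss weights
restored) and at most 500 epochs. Performance is the mean held-out accuracy
over stratified 10-fold cross-validation; accuracy is the only metric
because every evaluated dataset is class-balanced.

Two augmentation placements are supported. ``leakage_mode="fold_internal"``
(the default) balances classes inside each training fold only, so no
generated sample ever interpolates across the train/test boundary.
``leakage_mode="pre_split"`` balances the whole dataset before splitting,
an arrangement some studies use when reporting cross-validated accuracy on
balanced data; it is kept available, and labelled, because interpolated
near-duplicates of test samples can then appear in training folds and
inflate accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .augmentation import AugmentationConfig, balance_classes
from .datasets import N_SCORES, TaskDataset
from .models import ModelSpec, build_model, get_variant
from .nn import Adam, Network

__all__ = [
    "PER_TASK_BATCH_SIZES",
    "TrainConfig",
    "CVReport",
    "stratified_kfold_indices",
    "train_model",
    "cross_validate",
    "run_all_tasks",
]

#: tuned batch size for each BBS task 1..14
PER_TASK_BATCH_SIZES = {
    1: 64, 2: 32, 3: 64, 4: 16, 5: 32, 6: 32, 7: 32,
    8: 64, 9: 32, 10: 64, 11: 64, 12: 64, 13: 64, 14: 64,
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and stopping settings.

    ``batch_size=None`` selects the per-task default. ``min_delta`` is the
    smallest loss decrease counted as an improvement for early stopping.
    ``monitor`` is ``train_loss`` by default (no validation split is carved
    out); ``val_loss`` holds out ``validation_fraction`` of the training
    data for monitoring only.
    """

    learning_rate: float = 1e-3
    batch_size: Optional[int] = None
    early_stop_patience: int = 20
    max_epochs: int = 500
    min_delta: float = 1e-3
    monitor: str = "train_loss"  # "train_loss" | "val_loss"
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.monitor not in ("train_loss", "val_loss"):
            raise ValueError(f"unknown monitor {self.monitor!r}")

    def batch_size_for_task(self, task_id: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return PER_TASK_BATCH_SIZES.get(task_id, 32)


@dataclass
class CVReport:
    """Fold-wise accuracies and their aggregates for one task and variant."""

    task_id: int
    variant: str
    fold_accuracies: list[float]
    fold_epochs: list[int]
    fold_times_s: list[float] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    @property
    def min_accuracy(self) -> float:
        return float(np.min(self.fold_accuracies))

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.fold_accuracies))

    @property
    def mean_epochs(self) -> float:
        return float(np.mean(self.fold_epochs))

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "variant": self.variant,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "fold_epochs": [int(e) for e in self.fold_epochs],
            "fold_times_s": [float(t) for t in self.fold_times_s],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "min_accuracy": self.min_accuracy,
            "max_accuracy": self.max_accuracy,
            "mean_epochs": self.mean_epochs,
        }


def stratified_kfold_indices(
    labels: np.ndarray, K: int, seed: int = 0
) -> list[np.ndarray]:
    """K disjoint test-index sets preserving per-class proportions.

    Each fold's per-class count differs from exact proportionality by less
    than one sample. Raises if any present class has fewer than K members.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < K]
    if too_small.size:
        raise ValueError(
            f"classes {too_small.tolist()} have fewer than K={K} samples"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _one_hot(labels: np.ndarray, n_classes: int = N_SCORES) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(labels, dtype=int)]


def train_model(
    model: Network,
    train_samples: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig,
    task_id: int = 0,
) -> tuple[Network, dict]:
    """Fit with Adam, early stopping, and best-weight restoration.

    Returns the model (weights restored to the best monitored epoch) and a
    history dict with per-epoch loss/accuracy, the stopping epoch (1-based
    count of epochs actually run) and the best epoch.
    """
    if len(train_samples) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    x, y = np.asarray(train_samples, dtype=float), np.asarray(train_labels, dtype=int)

    if config.monitor == "val_loss":
        n_val = max(1, int(round(config.validation_fraction * len(x))))
        perm = rng.permutation(len(x))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_val, y_val = x[val_idx], _one_hot(y[val_idx])
        x, y_int = x[tr_idx], y[tr_idx]
    else:
        x_val = None
        y_int = y
    onehot = _one_hot(y_int)

    optimizer = Adam(model, learning_rate=config.learning_rate)
    batch = config.batch_size_for_task(task_id)
    history: dict = {"loss": [], "accuracy": [], "monitored": []}
    best = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    wait = 0
    epochs_run = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            losses.append(model.train_batch(x[idx], onehot[idx]))
            optimizer.step()
        epoch_loss = float(np.mean(losses))
        if config.monitor == "val_loss":
            from .nn import softmax_cross_entropy

            logits = model.trunk.forward(x_val, train=False)
            monitored = softmax_cross_entropy(logits, y_val)[0]
        else:
            monitored = epoch_loss
        acc = float(np.mean(model.predict(x) == y_int))
        history["loss"].append(epoch_loss)
        history["monitored"].append(monitored)
        history["accuracy"].append(acc)
        epochs_run = epoch
        if monitored < best - config.min_delta:
            best = monitored
            best_weights = model.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break

    model.set_weights(best_weights)
    history["stopped_epoch"] = epochs_run
    history["best_epoch"] = best_epoch
    return model, history


def cross_validate(
    spec: ModelSpec | str,
    dataset: TaskDataset,
    K: int = 10,
    train_config: TrainConfig = TrainConfig(),
    augmentation_config: AugmentationConfig | None = None,
    leakage_mode: str = "fold_internal",
) -> CVReport:
    """Stratified K-fold accuracy of one model variant on one task.

    A master seed fans out into the split seed, per-fold weight-init seeds,
    per-fold augmentation seeds and per-fold shuffle seeds, so a report is
    bit-reproducible from ``(dataset, configs)``.
    """
    import time

    if isinstance(spec, str):
        spec = get_variant(spec)
    if K < 2:
        raise ValueError("K must be >= 2")
    if leakage_mode not in ("fold_internal", "pre_split"):
        raise ValueError(f"unknown leakage_mode {leakage_mode!r}")

    master = np.random.default_rng(train_config.seed)
    split_seed = int(master.integers(2**31))
    fold_seeds = master.integers(2**31, size=(K, 3))

    if leakage_mode == "pre_split" and augmentation_config is not None:
        dataset = balance_classes(dataset, augmentation_config)

    folds = stratified_kfold_indices(dataset.labels, K, seed=split_seed)
    all_idx = np.arange(len(dataset))
    accs: list[float] = []
    epochs: list[int] = []
    times: list[float] = []
    input_shape = (dataset.time_length, dataset.n_channels)

    for fold_i, test_idx in enumerate(folds):
        t0 = time.perf_counter()
        train_idx = np.setdiff1d(all_idx, test_idx)
        x_train = dataset.samples[train_idx]
        y_train = dataset.labels[train_idx]
        if leakage_mode == "fold_internal" and augmentation_config is not None:
            fold_ds = TaskDataset(
                x_train, y_train, dataset.task_id, dataset.sampling_rate_hz
            )
            aug = replace(
                augmentation_config, seed=int(fold_seeds[fold_i, 1])
            )
            fold_ds = balance_classes(fold_ds, aug)
            x_train, y_train = fold_ds.samples, fold_ds.labels

        model = build_model(spec, input_shape, seed=int(fold_seeds[fold_i, 0]))
        fold_cfg = replace(train_config, seed=int(fold_seeds[fold_i, 2]))
        model, history = train_model(
            model, x_train, y_train, fold_cfg, task_id=dataset.task_id
        )
        pred = model.predict(dataset.samples[test_idx])
        accs.append(float(np.mean(pred == dataset.labels[test_idx])))
        epochs.append(history["stopped_epoch"])
        times.append(time.perf_counter() - t0)

    return CVReport(
        task_id=dataset.task_id,
        variant=spec.variant,
        fold_accuracies=accs,
        fold_epochs=epochs,
        fold_times_s=times,
    )


def run_all_tasks(
    corpus: dict[int, TaskDataset],
    variant: ModelSpec | str,
    K: int = 10,
    train_config: TrainConfig = TrainConfig(),
    augmentation_config: AugmentationConfig | None = None,
    leakage_mode: str = "fold_internal",
) -> dict:
    """Per-task CV reports plus the grand mean/std across all 14 tasks.

    The grand std is the population standard deviation of the 14 per-task
    mean accuracies.
    """
    missing = [t for t in range(1, 15) if t not in corpus]
    if missing:
        raise ValueError(f"corpus is missing tasks {missing}")
    reports = {}
    for task_id in sorted(corpus):
        reports[task_id] = cross_validate(
            variant,
            corpus[task_id],
            K=K,
            train_config=train_config,
            augmentation_config=augmentation_config,
            leakage_mode=leakage_mode,
        )
    means = np.array([r.mean_accuracy for r in reports.values()])
    return {
        "reports": reports,
        "grand_mean_accuracy": float(means.mean()),
        "grand_std_accuracy": float(means.std()),
    }
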