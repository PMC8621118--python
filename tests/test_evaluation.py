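"""Stratified splitting, early stopping and cross-validation plumbing."""

import numpy as np
import pytest

from bbscore.augmentation import AugmentationConfig
from bbscore.datasets import TaskDataset
from bbscore.evaluation import (
    PER_TASK_BATCH_SIZES,
    CVReport,
    TrainConfig,
    cross_validate,
    run_all_tasks,
    stratified_kfold_indices,
    train_model,
)
from bbscore.models import build_model, get_variant


class TestStratifiedFolds:
    def test_balanced_divisible_case(self):
        labels = np.repeat(np.arange(5), 60)
        folds = stratified_kfold_indices(labels, 10, seed=0)
        for fold in folds:
            assert len(fold) == 30
            _, counts = np.unique(labels[fold], return_counts=True)
            assert list(counts) == [6] * 5

    def test_partition_property(self):
        labels = np.repeat([0, 1, 2], [50, 30, 20])
        folds = stratified_kfold_indices(labels, 10, seed=1)
        joined = np.concatenate(folds)
        assert len(joined) == 100
        assert len(np.unique(joined)) == 100

    def test_proportions_within_one_sample(self):
        labels = np.repeat([0, 1, 2], [50, 30, 20])
        folds = stratified_kfold_indices(labels, 10, seed=2)
        for fold in folds:
            _, counts = np.unique(labels[fold], return_counts=True)
            assert list(counts) == [5, 3, 2]

    def test_small_class_rejected(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than K"):
            stratified_kfold_indices(labels, 10)

    def test_reproducible(self):
        labels = np.repeat(np.arange(5), 12)
        f1 = stratified_kfold_indices(labels, 5, seed=3)
        f2 = stratified_kfold_indices(labels, 5, seed=3)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)


def _tiny_dataset(n_per_class=6, t=8, ch=72, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    samples, labels = [], []
    for score in range(5):
        for _ in range(n_per_class):
            x = rng.standard_normal((t, ch)) * 0.1
            if signal:
                x[:, : 14 * (score + 1)] += 1.0  # crude, strongly separable cue
            samples.append(x)
            labels.append(score)
    return TaskDataset(np.stack(samples), np.array(labels), task_id=1)


class TestTraining:
    def test_empty_training_set_rejected(self):
        model = build_model(get_variant("C"), (8, 72), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_model(model, np.zeros((0, 8, 72)), np.zeros(0, dtype=int), TrainConfig())

    def test_early_stopping_arithmetic(self):
        """With a frozen, dropout-free model the loss never improves, so
        training stops after exactly 1 + patience epochs."""
        import dataclasses

        ds = _tiny_dataset()
        spec = dataclasses.replace(get_variant("C"), dropout_rate=0.0)
        model = build_model(spec, (8, 72), seed=0)
        cfg = TrainConfig(
            learning_rate=0.0, early_stop_patience=5, max_epochs=100, batch_size=64
        )
        _, history = train_model(model, ds.samples, ds.labels, cfg)
        assert history["stopped_epoch"] == 6
        assert history["best_epoch"] == 1

    def test_patience_validated(self):
        with pytest.raises(ValueError, match="patience"):
            TrainConfig(early_stop_patience=500, max_epochs=500)

    def test_best_weights_restored(self):
        ds = _tiny_dataset()
        model = build_model(get_variant("C"), (8, 72), seed=1)
        cfg = TrainConfig(max_epochs=30, early_stop_patience=5, seed=2)
        model, history = train_model(model, ds.samples, ds.labels, cfg)
        # the restored model's loss equals the best monitored loss
        from bbscore.nn import softmax_cross_entropy

        logits = model.trunk.forward(ds.samples, train=False)
        onehot = np.eye(5)[ds.labels]
        loss = softmax_cross_entropy(logits, onehot)[0]
        assert loss <= min(history["monitored"]) + 1e-6

    def test_capacity_on_separable_data(self):
        ds = _tiny_dataset(n_per_class=10)
        model = build_model(get_variant("C"), (8, 72), seed=3)
        cfg = TrainConfig(max_epochs=200, seed=4, batch_size=32)
        model, history = train_model(model, ds.samples, ds.labels, cfg)
        assert history["accuracy"][-1] >= 0.99

    def test_per_task_batch_sizes(self):
        assert PER_TASK_BATCH_SIZES[4] == 16
        assert TrainConfig().batch_size_for_task(4) == 16
        assert TrainConfig(batch_size=8).batch_size_for_task(4) == 8


class TestCrossValidate:
    def test_report_structure_and_aggregates(self):
        ds = _tiny_dataset(n_per_class=6)
        cfg = TrainConfig(max_epochs=25, early_stop_patience=5, seed=0, batch_size=32)
        report = cross_validate("C", ds, K=3, train_config=cfg)
        assert len(report.fold_accuracies) == 3
        assert report.mean_accuracy == pytest.approx(np.mean(report.fold_accuracies))
        assert report.std_accuracy == pytest.approx(np.std(report.fold_accuracies))
        assert report.min_accuracy == min(report.fold_accuracies)
        assert report.max_accuracy == max(report.fold_accuracies)

    def test_fold_internal_augmentation_has_no_leakage(self):
        """Provenance parents of generated samples always lie inside the
        training split (indices below the training-split size)."""
        ds = _tiny_dataset(n_per_class=6)
        captured = []

        import bbscore.evaluation as ev

        original = ev.balance_classes

        def spy(dataset, config):
            out = original(dataset, config)
            captured.append((len(dataset), out.provenance))
            return out

        ev.balance_classes, saved = spy, original
        try:
            cross_validate(
                "C",
                ds,
                K=3,
                train_config=TrainConfig(
                    max_epochs=6, early_stop_patience=2, seed=0, batch_size=32
                ),
                augmentation_config=AugmentationConfig(k=2, target_per_class_N=8),
                leakage_mode="fold_internal",
            )
        finally:
            ev.balance_classes = saved
        assert captured
        for n_train, provenance in captured:
            assert provenance
            for rec in provenance:
                assert rec["parent_index"] < n_train
                assert rec["neighbour_index"] < n_train

    def test_pre_split_mode_balances_before_folding(self):
        ds = _tiny_dataset(n_per_class=6)
        report = cross_validate(
            "C",
            ds,
            K=5,
            train_config=TrainConfig(
                max_epochs=6, early_stop_patience=2, seed=0, batch_size=32
            ),
            augmentation_config=AugmentationConfig(k=2, target_per_class_N=10),
            leakage_mode="pre_split",
        )
        # 5 classes x 10 samples split into 5 folds of 10
        assert len(report.fold_accuracies) == 5

    def test_deterministic_given_seed(self):
        ds = _tiny_dataset(n_per_class=6)
        cfg = TrainConfig(max_epochs=8, early_stop_patience=3, seed=5, batch_size=32)
        r1 = cross_validate("C", ds, K=3, train_config=cfg)
        r2 = cross_validate("C", ds, K=3, train_config=cfg)
        assert r1.fold_accuracies == r2.fold_accuracies


class TestRunAll:
    def test_missing_tasks_listed(self):
        ds = _tiny_dataset()
        with pytest.raises(ValueError, match=r"\[2"):
            run_all_tasks({1: ds}, "C")

    def test_grand_aggregation(self):
        corpus = {
            t: TaskDataset(
                _tiny_dataset(n_per_class=4, seed=t).samples,
                _tiny_dataset(n_per_class=4, seed=t).labels,
                task_id=t,
            )
            for t in range(1, 15)
        }
        cfg = TrainConfig(max_epochs=3, early_stop_patience=1, seed=0, batch_size=32)
        summary = run_all_tasks(corpus, "C", K=2, train_config=cfg)
        means = [r.mean_accuracy for r in summary["reports"].values()]
        assert summary["grand_mean_accuracy"] == pytest.approx(np.mean(means))
        assert summary["grand_std_accuracy"] == pytest.approx(np.std(means))
        assert len(summary["reports"]) == 14


def test_cvreport_serialization_consistency():
    report = CVReport(1, "C", [0.5, 0.7], [10, 12], [1.0, 1.1])
    d = report.to_dict()
    assert d["mean_accuracy"] == pytest.approx(0.6)
    assert d["fold_epochs"] == [10, 12]
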