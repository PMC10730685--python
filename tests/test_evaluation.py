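import numpy as np
import pytest

from edapain.evaluation import (
    TASKS,
    FoldReport,
    SplitError,
    TaskError,
    TaskSpec,
    TrainConfig,
    binary_confusion,
    compute_metrics,
    fit_scaler,
    loocv_split,
    make_task,
    roc_curve,
    summarize_folds,
    train_model,
)
from edapain.model import small_model_config


def brute_force_metrics(y_true, y_pred):
    """Confusion-matrix metric formulas evaluated by explicit counting."""
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    prec1 = tp / (tp + fp) if tp + fp else 0.0
    rec1 = tp / (tp + fn) if tp + fn else 0.0
    f1_1 = 2 * prec1 * rec1 / (prec1 + rec1) if prec1 + rec1 else 0.0
    prec0 = tn / (tn + fn) if tn + fn else 0.0
    rec0 = tn / (tn + fp) if tn + fp else 0.0
    f1_0 = 2 * prec0 * rec0 / (prec0 + rec0) if prec0 + rec0 else 0.0
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = (acc - pe) / (1 - pe) if pe != 1 else 0.0
    return {
        "accuracy": acc,
        "macro_f1": (f1_0 + f1_1) / 2,
        "kappa": kappa,
        "specificity": rec0,
        "sensitivity": rec1,
    }


def mann_whitney_auc(scores, y):
    """O(n^2) pairwise comparison with midrank tie handling."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestTasks:
    def test_t0_vs_t4_counts(self, tiny_protocol, tiny_cohort):
        X, y, sids = make_task(tiny_cohort, "T0_vs_T4")
        n_sub, reps = tiny_protocol.n_subjects, tiny_protocol.reps_per_class
        assert len(X) == 2 * reps * n_sub
        assert y.sum() == reps * n_sub

    def test_t0_vs_all_imbalance(self, tiny_cohort):
        _, y, _ = make_task(tiny_cohort, "T0_vs_all")
        assert y.sum() == 4 * (len(y) - y.sum())

    def test_overlapping_label_sets_rejected(self):
        with pytest.raises(TaskError, match="overlap"):
            TaskSpec("bad", frozenset({1, 2}), frozenset({0, 1}))

    def test_named_tasks_cover_paper_suite(self):
        assert set(TASKS) == {
            "T0_vs_all", "T0_vs_T1", "T0_vs_T2", "T0_vs_T3", "T0_vs_T4"
        }


class TestLoocvSplit:
    def test_three_subject_enumeration(self):
        folds = loocv_split(["a", "b", "c"])
        assert [t for _, t in folds] == ["a", "b", "c"]
        assert folds[0][0] == ["b", "c"]

    def test_partition_property(self):
        ids = [f"S{i:03d}" for i in range(1, 21)]
        folds = loocv_split(ids)
        assert len(folds) == 20
        held = [t for _, t in folds]
        assert sorted(held) == sorted(ids)
        for train_ids, test_id in folds:
            assert test_id not in train_ids
            assert sorted(train_ids + [test_id]) == sorted(ids)

    def test_single_subject_rejected(self):
        with pytest.raises(SplitError):
            loocv_split(["only"])


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = compute_metrics(y, y, y.astype(float))
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0
        assert m["kappa"] == 1.0 and m["auc"] == 1.0

    def test_all_positive_predictions_on_imbalanced_task(self):
        """Predicting pain everywhere: sensitivity 100, specificity 0."""
        y = np.array([0] * 20 + [1] * 80)
        p = np.ones_like(y)
        m = compute_metrics(y, p)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 0.8

    def test_matches_brute_force_formulas_on_random_instances(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, 200)
            p = rng.integers(0, 2, 200)
            m = compute_metrics(y, p)
            b = brute_force_metrics(y, p)
            for key, val in b.items():
                assert m[key] == pytest.approx(val, abs=1e-12), key

    def test_single_class_truth_has_undefined_auc(self):
        m = compute_metrics(np.ones(5, dtype=int), np.ones(5, dtype=int),
                            np.linspace(0, 1, 5))
        assert np.isnan(m["auc"])

    def test_empty_input_rejected(self):
        with pytest.raises(TaskError):
            compute_metrics(np.array([]), np.array([]))


class TestRoc:
    def test_scores_equal_truth_give_unit_auc(self):
        y = np.array([0, 1, 0, 1])
        *_, auc = roc_curve(y.astype(float), y)
        assert auc == 1.0

    def test_independent_scores_near_half(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        *_, auc = roc_curve(s, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_mann_whitney(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(40), 1)  # coarse grid to exercise ties
            *_, auc = roc_curve(s, y)
            assert auc == pytest.approx(mann_whitney_auc(s, y), abs=1e-9)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(TaskError):
            roc_curve(np.array([0.2, 0.4]), np.array([1, 1]))


class TestFoldAggregation:
    def _folds(self, rng, n=4):
        out = []
        for i in range(n):
            y = rng.integers(0, 2, 30)
            s = rng.random(30)
            out.append(FoldReport(f"S{i}", y, (s > 0.5).astype(int), s, seed=i))
        return out

    def test_pooled_confusion_is_sum_of_fold_confusions(self, rng):
        folds = self._folds(rng)
        rep = summarize_folds("T0_vs_T4", folds, seed=0)
        total = sum(binary_confusion(f.y_true, f.y_pred) for f in folds)
        np.testing.assert_array_equal(rep.confusion, total)

    def test_per_fold_mean_mode_differs_from_pooled(self, rng):
        folds = self._folds(rng)
        pooled = summarize_folds("t", folds, 0, "pooled")
        per = summarize_folds("t", folds, 0, "per_fold_mean")
        assert per.metric_mode == "per_fold_mean"
        assert pooled.accuracy == pytest.approx(
            np.concatenate([f.y_true == f.y_pred for f in folds]).mean()
        )
        assert per.accuracy == pytest.approx(
            np.mean([(f.y_true == f.y_pred).mean() for f in folds])
        )


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, tiny_cohort):
        """A few epochs on separable synthetic data reduce the training loss."""
        X, y, _ = make_task(tiny_cohort, "T0_vs_T4")
        cfg = TrainConfig(batch_size=8, epochs=3, seed=1)
        model, scaler, losses = train_model(X, y, small_model_config(), cfg)
        assert losses[-1] < losses[0]
        assert np.all(np.isfinite(losses))

    def test_scaler_centers_segments(self, rng):
        X = rng.standard_normal((10, 50)).astype(np.float32) + 7.0
        scaler = fit_scaler(X)
        Xs = scaler(X)
        np.testing.assert_allclose(Xs.mean(axis=1), 0.0, atol=1e-5)
        assert Xs.std() == pytest.approx(1.0, abs=0.05)

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(weight_decay=-1.0)
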