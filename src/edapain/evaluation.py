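"""Task construction, leave-one-subject-out evaluation, and macro metrics.

Binary tasks contrast the pain-free class T0 with single pain levels or with
all of them pooled.  Evaluation is subject-level leave-one-out: each subject
is held out once, the model is trained on the rest, and the held-out
predictions from all folds are pooled before computing accuracy, macro F1,
Cohen's kappa, specificity, sensitivity and ROC AUC (a per-fold-mean mode is
also available).  One master seed fans out per-fold seeds deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .model import ModelConfig, PainIntensityClassifier, build_model
from .nn import reseed_dropout, softmax_cross_entropy
from .simulate import Cohort


class TaskError(ValueError):
    """Invalid or empty task construction."""


class SplitError(ValueError):
    """Cross-validation split cannot be formed."""


class TrainingError(RuntimeError):
    """Optimization produced a non-finite loss."""


@dataclass(frozen=True)
class TaskSpec:
    name: str
    positive_labels: frozenset[int]
    negative_labels: frozenset[int]

    def __post_init__(self) -> None:
        if self.positive_labels & self.negative_labels:
            raise TaskError(f"{self.name}: label sets overlap")
        union = self.positive_labels | self.negative_labels
        if not union <= {0, 1, 2, 3, 4}:
            raise TaskError(f"{self.name}: labels outside 0..4")
        if not self.positive_labels or not self.negative_labels:
            raise TaskError(f"{self.name}: both label sets must be nonempty")


TASKS: dict[str, TaskSpec] = {
    "T0_vs_all": TaskSpec("T0_vs_all", frozenset({1, 2, 3, 4}), frozenset({0})),
    "T0_vs_T1": TaskSpec("T0_vs_T1", frozenset({1}), frozenset({0})),
    "T0_vs_T2": TaskSpec("T0_vs_T2", frozenset({2}), frozenset({0})),
    "T0_vs_T3": TaskSpec("T0_vs_T3", frozenset({3}), frozenset({0})),
    "T0_vs_T4": TaskSpec("T0_vs_T4", frozenset({4}), frozenset({0})),
}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "learning_rate", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def small_train_config(epochs: int = 10, seed: int = 0) -> TrainConfig:
    """Desk-scale recipe for small synthetic cohorts."""
    return TrainConfig(batch_size=16, epochs=epochs, seed=seed)


@dataclass
class FoldReport:
    held_out_subject: str
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # positive-class probabilities
    seed: int
    losses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.y_true) == len(self.y_pred) == len(self.scores)):
            raise ValueError("fold arrays must have equal lengths")


@dataclass
class RunReport:
    task: str
    folds: list[FoldReport]
    confusion: np.ndarray
    accuracy: float
    macro_f1: float
    kappa: float
    specificity: float
    sensitivity: float
    auc: float
    metric_mode: str
    seed: int

    def pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        y = np.concatenate([f.y_true for f in self.folds])
        p = np.concatenate([f.y_pred for f in self.folds])
        s = np.concatenate([f.scores for f in self.folds])
        return y, p, s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "task": self.task,
                    "specificity": self.specificity,
                    "sensitivity": self.sensitivity,
                    "accuracy": self.accuracy,
                    "macro_f1": self.macro_f1,
                    "kappa": self.kappa,
                    "auc": self.auc,
                    "n_folds": len(self.folds),
                    "metric_mode": self.metric_mode,
                    "seed": self.seed,
                }
            ]
        )


# -- task construction -------------------------------------------------------

def make_task(
    cohort: Cohort, spec: TaskSpec | str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relabel a cohort for one binary task.

    Returns (X, y, subject_ids) with y in {0, 1}; segments whose class is in
    neither label set are dropped.
    """
    if isinstance(spec, str):
        spec = TASKS[spec]
    X, labels, sids = cohort.to_arrays()
    pos = np.isin(labels, list(spec.positive_labels))
    neg = np.isin(labels, list(spec.negative_labels))
    keep = pos | neg
    if not pos.any() or not neg.any():
        raise TaskError(f"{spec.name}: a class is empty after filtering")
    y = pos[keep].astype(np.int64)
    return X[keep], y, sids[keep]


def loocv_split(subjects) -> list[tuple[list[str], str]]:
    """Leave-one-subject-out folds: each subject is the test set exactly once."""
    if isinstance(subjects, Cohort):
        ids = [p.subject_id for p in subjects.subjects]
    else:
        ids = list(dict.fromkeys(subjects))
    if len(ids) < 2:
        raise SplitError("leave-one-out needs at least 2 subjects")
    return [([s for s in ids if s != held], held) for held in ids]


# -- training ----------------------------------------------------------------

@dataclass(frozen=True)
class Scaler:
    """Per-segment mean removal plus a global train-set scale."""

    std: float

    def __call__(self, X: np.ndarray) -> np.ndarray:
        Xc = X - X.mean(axis=1, keepdims=True)
        return (Xc / self.std).astype(np.float32)


def fit_scaler(X: np.ndarray) -> Scaler:
    Xc = X - X.mean(axis=1, keepdims=True)
    std = float(Xc.std())
    return Scaler(std=std if std > 0 else 1.0)


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seed: int | None = None,
) -> tuple[PainIntensityClassifier, Scaler, list[float]]:
    """Fit the classifier on (already task-relabelled) segments.

    Returns the final-epoch model (no inner validation split is used), the
    input scaler fitted on the training data, and per-epoch mean losses.
    """
    from .nn.optim import Adam

    seed = train_cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    init_ss, shuffle_ss, drop_ss = ss.spawn(3)
    rng = np.random.default_rng(shuffle_ss)

    scaler = fit_scaler(X)
    Xs = scaler(X)
    model = build_model(model_cfg, Xs.shape[1], seed=init_ss.generate_state(1)[0] % (2**31))
    reseed_dropout(model, drop_ss)
    model.train()
    opt = Adam(
        model.parameters(),
        lr=train_cfg.learning_rate,
        betas=train_cfg.betas,
        eps=train_cfg.eps,
        weight_decay=train_cfg.weight_decay,
    )
    weights = None
    if train_cfg.class_weighting:
        counts = np.bincount(y, minlength=model_cfg.n_classes).astype(float)
        weights = counts.sum() / (len(counts) * np.maximum(counts, 1.0))

    n = len(Xs)
    losses = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb, yb = Xs[idx], y[idx]
            logits = model(xb)
            loss, dlogits, _ = softmax_cross_entropy(logits, yb)
            if weights is not None:
                w = weights[yb] / weights[yb].mean()
                dlogits *= w[:, None]
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {start // train_cfg.batch_size}"
                )
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    model.eval()
    return model, scaler, losses


def predict_proba(
    model: PainIntensityClassifier, scaler: Scaler, X: np.ndarray, batch_size: int = 64
) -> np.ndarray:
    from .nn import softmax

    model.eval()
    Xs = scaler(X)
    out = []
    for start in range(0, len(Xs), batch_size):
        out.append(softmax(model(Xs[start : start + batch_size]), axis=-1))
    return np.concatenate(out, axis=0)


def train_fold(
    X: np.ndarray,
    y: np.ndarray,
    sids: np.ndarray,
    held_out: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    fold_seed: int,
) -> FoldReport:
    test = sids == held_out
    model, scaler, losses = train_model(
        X[~test], y[~test], model_cfg, train_cfg, seed=fold_seed
    )
    probs = predict_proba(model, scaler, X[test])
    scores = probs[:, 1]
    return FoldReport(
        held_out_subject=held_out,
        y_true=y[test],
        y_pred=(scores >= 0.5).astype(np.int64),
        scores=scores,
        seed=fold_seed,
        losses=losses,
    )


# -- metrics -----------------------------------------------------------------

def binary_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    return skm.confusion_matrix(y_true, y_pred, labels=[0, 1])


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """Accuracy, macro F1, Cohen's kappa, specificity, sensitivity, AUC.

    Sensitivity is recall on the positive (pain) class, specificity recall on
    the negative (pain-free) class.  AUC is reported as NaN when only one
    class is present in the truth.
    """
    if len(y_true) == 0:
        raise TaskError("cannot compute metrics on empty predictions")
    cm = binary_confusion(y_true, y_pred)
    tn, fp, fn, tp = cm.ravel()
    out = {
        "accuracy": skm.accuracy_score(y_true, y_pred),
        "macro_f1": skm.f1_score(y_true, y_pred, average="macro", zero_division=0),
        "kappa": skm.cohen_kappa_score(y_true, y_pred, labels=[0, 1]),
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
    }
    if scores is None or len(np.unique(y_true)) < 2:
        out["auc"] = np.nan
    else:
        out["auc"] = skm.roc_auc_score(y_true, scores)
    return out


def roc_curve(
    scores: np.ndarray, y_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep plus trapezoidal AUC.

    The AUC equals the Mann-Whitney U statistic with midrank tie handling.
    """
    if len(np.unique(y_true)) < 2:
        raise TaskError("ROC is undefined with a single class in the truth")
    fpr, tpr, thresholds = skm.roc_curve(y_true, scores)
    return fpr, tpr, thresholds, float(skm.auc(fpr, tpr))


def run_loocv(
    cohort: Cohort,
    task: TaskSpec | str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    metric_mode: str = "pooled",
    progress: bool = False,
) -> RunReport:
    """Full leave-one-subject-out evaluation of one binary task."""
    if metric_mode not in ("pooled", "per_fold_mean"):
        raise ValueError("metric_mode must be 'pooled' or 'per_fold_mean'")
    spec = TASKS[task] if isinstance(task, str) else task
    X, y, sids = make_task(cohort, spec)
    folds = loocv_split([p.subject_id for p in cohort.subjects])
    fold_seeds = [
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(train_cfg.seed).spawn(len(folds))
    ]
    reports = []
    for (train_ids, held), fseed in zip(folds, fold_seeds):
        if progress:
            print(f"[{spec.name}] fold {held} ({len(reports) + 1}/{len(folds)})")
        reports.append(
            train_fold(X, y, sids, held, model_cfg, train_cfg, fseed)
        )
    return summarize_folds(spec.name, reports, train_cfg.seed, metric_mode)


def summarize_folds(
    task_name: str, reports: list[FoldReport], seed: int, metric_mode: str = "pooled"
) -> RunReport:
    y = np.concatenate([f.y_true for f in reports])
    p = np.concatenate([f.y_pred for f in reports])
    s = np.concatenate([f.scores for f in reports])
    if metric_mode == "pooled":
        m = compute_metrics(y, p, s)
    else:
        per = [
            compute_metrics(f.y_true, f.y_pred, f.scores)
            for f in reports
        ]
        m = {k: float(np.nanmean([d[k] for d in per])) for k in per[0]}
    return RunReport(
        task=task_name,
        folds=reports,
        confusion=binary_confusion(y, p),
        accuracy=m["accuracy"],
        macro_f1=m["macro_f1"],
        kappa=m["kappa"],
        specificity=m["specificity"],
        sensitivity=m["sensitivity"],
        auc=m["auc"],
        metric_mode=metric_mode,
        seed=seed,
    )
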