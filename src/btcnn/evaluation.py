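"""5-fold cross-validation harness and multiclass metrics.

The protocol mirrors the published experiment: stratified 5-fold
splitting, per-fold training, confusion matrices and per-class
precision/recall/F1, and cross-fold mean/standard deviation of the train
and test accuracies.  Two report bases are emitted per fold: metrics on
the held-out fifth, and correct-classification counts over the whole
dataset (the published per-fold class counts approach full-dataset class
sizes, so both conventions are kept).

Accuracy = trace/total; precision = TP/(TP+FP); recall = TP/(TP+FN);
F1 = 2PR/(P+R); macro averages are unweighted means over classes.
Zero-denominator metrics are reported as 0 and flagged.  Cross-fold
standard deviations use the sample (n-1) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from .archspec import BTCNNSpec
from .netcore.estimator import BTCNNClassifier

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "FoldResult",
    "CrossFoldSummary",
    "kfold_split",
    "confusion",
    "metrics_from_confusion",
    "aggregate",
    "run_cross_validation",
]


@dataclass(frozen=True)
class FoldPlan:
    """Per-example fold assignment; every example is in exactly one fold."""

    n_folds: int
    assignments: np.ndarray
    stratified: bool
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_folds)


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    correct_per_class: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    zero_division_flags: np.ndarray  # classes where a denominator was 0


@dataclass(frozen=True)
class FoldResult:
    fold: int
    train_accuracy: float
    test_accuracy: float
    heldout_confusion: ConfusionMatrix
    heldout_metrics: MetricsReport
    full_confusion: ConfusionMatrix
    full_metrics: MetricsReport


@dataclass(frozen=True)
class CrossFoldSummary:
    folds: tuple[FoldResult, ...]
    train_accuracy_mean: float
    train_accuracy_sd: float
    test_accuracy_mean: float
    test_accuracy_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": [f.fold for f in self.folds],
                "train_acc": [f.train_accuracy for f in self.folds],
                "test_acc": [f.test_accuracy for f in self.folds],
            }
        )


def kfold_split(
    labels, n_folds: int = 5, stratified: bool = True, seed: int = 0
) -> FoldPlan:
    """Partition example indices into near-equal folds, deterministically.

    Stratified by default so per-class counts differ by at most one
    across folds.
    """
    y = np.asarray(labels)
    if y.ndim == 2:
        y = y.argmax(axis=1)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if stratified:
        counts = np.bincount(y)
        if counts[counts > 0].min() < n_folds:
            raise ValueError(
                f"stratified split needs >= {n_folds} examples in every class"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        if len(y) < n_folds:
            raise ValueError(f"need at least {n_folds} examples")
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        assignments[test_idx] = fold
    return FoldPlan(n_folds=n_folds, assignments=assignments, stratified=stratified, seed=seed)


def confusion(true, predicted, n_classes: int) -> ConfusionMatrix:
    """counts[i, j] = number of examples with true class i predicted as j."""
    t = np.asarray(true, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted lengths differ")
    if t.size and (t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes):
        raise ValueError("class index outside [0, n_classes)")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus macro averages."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    pred_pos = counts.sum(axis=0).astype(float)
    actual_pos = counts.sum(axis=1).astype(float)
    flags = (pred_pos == 0) | (actual_pos == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 0.0)
        recall = np.where(actual_pos > 0, tp / np.maximum(actual_pos, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        correct_per_class=np.diag(counts).copy(),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        zero_division_flags=flags,
    )


def aggregate(values) -> tuple[float, float]:
    """(arithmetic mean, sample standard deviation) of per-fold values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def run_cross_validation(
    images: np.ndarray,
    labels: np.ndarray,
    spec: BTCNNSpec,
    *,
    epochs: int = 20,
    batch_size: int = 24,
    learning_rate: float = 1e-4,
    n_folds: int = 5,
    stratified: bool = True,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
    estimator: BTCNNClassifier | None = None,
) -> CrossFoldSummary:
    """Train/evaluate one estimator per fold and aggregate across folds.

    ``labels`` may be one-hot rows or integer indices.  Each fold trains
    on the other ``n_folds - 1`` folds and reports accuracy on its
    held-out fold plus confusion counts over both the held-out fold and
    the whole dataset.
    """
    y = np.asarray(labels)
    if y.ndim == 2:
        y = y.argmax(axis=1)
    n_classes = spec.n_classes
    plan = fold_plan or kfold_split(y, n_folds=n_folds, stratified=stratified, seed=seed)
    base = estimator or BTCNNClassifier(
        spec=spec,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        random_state=seed,
    )
    results = []
    for fold in range(plan.n_folds):
        train_idx, test_idx = plan.fold_indices(fold)
        model = clone(base)
        model.set_params(random_state=seed + fold)
        model.fit(images[train_idx], y[train_idx])
        train_pred = model.predict(images[train_idx])
        test_pred = model.predict(images[test_idx])
        full_pred = np.empty(len(y), dtype=int)
        full_pred[train_idx] = train_pred
        full_pred[test_idx] = test_pred
        heldout_cm = confusion(y[test_idx], test_pred, n_classes)
        full_cm = confusion(y, full_pred, n_classes)
        results.append(
            FoldResult(
                fold=fold,
                train_accuracy=float((train_pred == y[train_idx]).mean()),
                test_accuracy=float((test_pred == y[test_idx]).mean()),
                heldout_confusion=heldout_cm,
                heldout_metrics=metrics_from_confusion(heldout_cm),
                full_confusion=full_cm,
                full_metrics=metrics_from_confusion(full_cm),
            )
        )
    train_mean, train_sd = aggregate([r.train_accuracy for r in results])
    test_mean, test_sd = aggregate([r.test_accuracy for r in results])
    return CrossFoldSummary(
        folds=tuple(results),
        train_accuracy_mean=train_mean,
        train_accuracy_sd=train_sd,
        test_accuracy_mean=test_mean,
        test_accuracy_sd=test_sd,
    )
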