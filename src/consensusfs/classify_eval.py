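"""Multi-classifier evaluation under stratified k-fold cross-validation.

Six standard binary classifiers (linear SVM, random forest, Gaussian naive
Bayes, a small neural network, k-nearest neighbours, logistic regression)
are trained on the expression matrix restricted to a selected probe panel.
Samples are partitioned into stratified folds; each sample is predicted
exactly once by a model trained on the remaining folds, with feature
standardization learned on the training folds only.  Predictions are pooled
into a single confusion matrix from which the four summary metrics are
computed:

    Sensitivity = TP/(TP+FN)      Specificity = TN/(TN+FP)
    Accuracy = (TP+TN)/total      F1 = 2*TP/(2*TP+FP+FN)

Pooling is the default because per-fold macro-averaging is unstable with
one or two controls per fold; macro-averaging is available via ``pooling``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_model import ExpressionMatrix, PhenotypeVector

logger = logging.getLogger("consensusfs")

MODEL_NAMES = ("svm", "rf", "nbayes", "nnet", "knn", "logistic")

# Table-row labels for the printed summary
_DISPLAY = {
    "svm": "SVM",
    "rf": "RF",
    "nbayes": "naive Bayes",
    "nnet": "NNT",
    "knn": "KNN",
    "logistic": "Logistic",
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity/Specificity/Accuracy/F1; ``None`` marks an undefined
    metric (zero denominator), never silently 0."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None


@dataclass
class CVReport:
    model_name: str
    folds: list[tuple[list[str], np.ndarray]]  # (test sample_ids, predictions)
    pooled: ConfusionCounts
    metrics: MetricSet
    seed: int


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """The four summary metrics; zero-denominator metrics are ``None``."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return MetricSet(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        accuracy=ratio(c.tp + c.tn, c.total),
        f1=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def stratified_folds(
    labels: PhenotypeVector, k: int, seed: int = 0
) -> list[list[str]]:
    """Partition samples into k test sets, stratified by class.

    Fold sizes differ by at most one, as do each class's per-fold counts;
    deterministic given the seed.  ``k`` may exceed the smaller class size
    (up to leave-one-out at ``k = n``).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = len(labels.sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    totals = np.zeros(k, dtype=int)
    for cls in (1, 0):
        idx = [i for i, y in enumerate(labels.labels) if y == cls]
        rng.shuffle(idx)
        q, r = divmod(len(idx), k)
        # hand this class's surplus to the currently smallest folds
        order = np.argsort(totals, kind="stable")
        counts = np.full(k, q)
        counts[order[:r]] += 1
        start = 0
        for f in range(k):
            take = counts[f]
            for i in idx[start : start + take]:
                folds[f].append(labels.sample_ids[i])
            totals[f] += take
            start += take
    return folds


def _make_model(name: str, seed: int):
    rs = seed % (2**31 - 1)
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=rs)
    if name == "nbayes":
        return GaussianNB()
    if name == "nnet":
        return MLPClassifier(hidden_layer_sizes=(8,), max_iter=5000, random_state=rs)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "logistic":
        return LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized
    raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")


def _pool_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def cross_validate(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    model_name: str,
    k: int = 10,
    seed: int = 0,
    folds: Sequence[Sequence[str]] | None = None,
    pooling: Literal["pooled", "macro"] = "pooled",
) -> CVReport:
    """Cross-validated evaluation of one classifier on the given panel matrix.

    The matrix should already be restricted to the selected probes.  The
    scaler and classifier are fit on the training folds only; predictions
    over all folds are pooled into one confusion matrix (or macro-averaged
    with ``pooling="macro"``).  Fully reproducible given the seed.
    """
    if matrix.n_probes == 0:
        raise ValueError("panel is empty; nothing to evaluate")
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not aligned; call align() first")
    labels.require_both_classes()
    if folds is None:
        folds = stratified_folds(labels, k, seed)
    X = matrix.values.T
    y = labels.labels
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}

    fold_records: list[tuple[list[str], np.ndarray]] = []
    fold_metrics: list[MetricSet] = []
    all_true: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    for test_ids in folds:
        test_idx = np.array([pos[s] for s in test_ids], dtype=int)
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        scaler = StandardScaler().fit(X[train_mask])
        model = _make_model(model_name, seed)
        model.fit(scaler.transform(X[train_mask]), y[train_mask])
        pred = np.asarray(model.predict(scaler.transform(X[test_idx])), dtype=int)
        fold_records.append((list(test_ids), pred))
        all_true.append(y[test_idx])
        all_pred.append(pred)
        fold_metrics.append(metrics_from_confusion(_pool_confusion(y[test_idx], pred)))

    pooled = _pool_confusion(np.concatenate(all_true), np.concatenate(all_pred))
    if pooling == "pooled":
        metrics = metrics_from_confusion(pooled)
    else:
        metrics = MetricSet(
            *(
                _mean_defined([getattr(m, f) for m in fold_metrics])
                for f in ("sensitivity", "specificity", "accuracy", "f1")
            )
        )
    return CVReport(model_name, fold_records, pooled, metrics, seed)


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def evaluate_all(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    panel: Sequence[str],
    k: int = 10,
    seed: int = 0,
    pooling: Literal["pooled", "macro"] = "pooled",
) -> list[CVReport]:
    """One cross-validated report per registered model, on shared folds."""
    sub = matrix.subset_probes(panel)
    folds = stratified_folds(labels, k, seed)
    return [
        cross_validate(sub, labels, name, k=k, seed=seed, folds=folds, pooling=pooling)
        for name in MODEL_NAMES
    ]


def summary_table(reports: Sequence[CVReport]) -> pd.DataFrame:
    """Model-by-metric summary (4 decimals): Sensitivity, Specificity,
    F1score, Accuracy."""

    def fmt(v: float | None) -> float | None:
        return round(v, 4) if v is not None else None

    return pd.DataFrame(
        [
            {
                "Model": _DISPLAY.get(r.model_name, r.model_name),
                "Sensitivity": fmt(r.metrics.sensitivity),
                "Specificity": fmt(r.metrics.specificity),
                "F1score": fmt(r.metrics.f1),
                "Accuracy": fmt(r.metrics.accuracy),
            }
            for r in reports
        ]
    )
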