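"""Cubic-SVM cross-validated evaluation and the summary metric set.

The classifier is a degree-3 polynomial-kernel SVM with one-vs-one
multi-class coding, box constraint 1, and an automatic kernel scale:
``gamma = 1 / s**2`` where ``s`` is the median pairwise Euclidean distance
over a seeded subsample of (standardized) training points. Features are
standardized with training-fold statistics only. Out-of-fold predictions
from a stratified seeded k-fold accumulate into a single confusion matrix
from which all metrics derive.

The kernel is evaluated as ``(gamma * <x, y> + 1) ** 3`` on precomputed
inner-product matrices; the feature-selection sweep exploits this by
updating the inner products incrementally over nested feature sets.

Metrics: accuracy (trace over total), macro average recall (AR), macro
average precision (AP), F1 = harmonic mean of AP and AR, and the geometric
mean of per-class recalls. A class that is never predicted contributes a
zero precision term; for balanced classes accuracy equals AR exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fusion import FeatureMatrix

__all__ = ["EvaluationReport", "cubic_svm_cv", "metrics", "kernel_scale"]

_SCALE_SUBSAMPLE = 256


@dataclass(frozen=True)
class EvaluationReport:
    """Cross-validated confusion matrix, derived metrics and fold bookkeeping."""

    confusion: NDArray[np.int64]
    accuracy: float
    average_recall: float
    average_precision: float
    f1_score: float
    geometric_mean: float
    fold_assignment: NDArray[np.int64]
    predictions: NDArray
    seed: int

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "average_recall": self.average_recall,
            "average_precision": self.average_precision,
            "f1_score": self.f1_score,
            "geometric_mean": self.geometric_mean,
        }


def scale_subsample_indices(n: int, seed: int) -> NDArray[np.intp]:
    """Rows used by the kernel-scale heuristic for an n-row training matrix."""
    rng = np.random.default_rng(seed)
    if n > _SCALE_SUBSAMPLE:
        return np.sort(rng.choice(n, _SCALE_SUBSAMPLE, replace=False))
    return np.arange(n)


def gamma_from_gram(ip: NDArray[np.float64], idx: NDArray[np.intp]) -> float:
    """Kernel coefficient from an inner-product matrix restricted to ``idx``.

    The scale is the median pairwise Euclidean distance among the selected
    rows; ``gamma = 1 / scale**2`` (unit scale if the points coincide).
    """
    sub = ip[np.ix_(idx, idx)]
    diag = np.diag(sub)
    d2 = np.maximum(diag[:, None] + diag[None, :] - 2.0 * sub, 0.0)
    d = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
    med = float(np.median(d)) if d.size else 0.0
    return 1.0 / med**2 if med > 0 else 1.0


def kernel_scale(X: NDArray[np.float64], seed: int) -> float:
    """Median pairwise Euclidean distance on a seeded subsample of rows."""
    X = np.asarray(X, dtype=np.float64)
    idx = scale_subsample_indices(X.shape[0], seed)
    gamma = gamma_from_gram(X @ X.T, idx)
    return 1.0 / np.sqrt(gamma)


def fit_predict_from_gram(
    ip_train: NDArray[np.float64],
    y_train: NDArray,
    ip_test_train: NDArray[np.float64],
    seed: int,
) -> NDArray:
    """Fit the cubic SVM on precomputed inner products and predict the test rows."""
    idx = scale_subsample_indices(ip_train.shape[0], seed)
    gamma = gamma_from_gram(ip_train, idx)
    k_train = (gamma * ip_train + 1.0) ** 3
    k_test = (gamma * ip_test_train + 1.0) ** 3
    clf = SVC(kernel="precomputed", C=1.0, cache_size=256)
    clf.fit(k_train, y_train)
    return clf.predict(k_test)


def cross_val_predictions(
    X: NDArray[np.float64],
    y: NDArray,
    folds: int = 10,
    seed: int = 0,
) -> tuple[NDArray, NDArray[np.int64]]:
    """Out-of-fold cubic-SVM predictions under stratified seeded k-fold CV."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has only {counts.min()} "
            f"observations, fewer than the {folds} folds requested; "
            "reduce the number of folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    fold_of = np.empty(y.shape[0], dtype=np.int64)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        Xtr = scaler.transform(X[tr])
        Xte = scaler.transform(X[te])
        pred[te] = fit_predict_from_gram(Xtr @ Xtr.T, y[tr], Xte @ Xtr.T, seed)
        fold_of[te] = fold
    return pred, fold_of


def cubic_svm_cv(
    features: FeatureMatrix | tuple[ArrayLike, ArrayLike],
    folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate a feature matrix with the cubic SVM under stratified CV."""
    if isinstance(features, FeatureMatrix):
        X, y = features.X, features.y
    else:
        X, y = features
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
    pred, fold_of = cross_val_predictions(X, y, folds=folds, seed=seed)
    labels = np.unique(y)
    conf = confusion_matrix(y, pred, labels=labels)
    acc, ar, ap, f1, gmean = metrics(conf)
    return EvaluationReport(
        confusion=conf,
        accuracy=acc,
        average_recall=ar,
        average_precision=ap,
        f1_score=f1,
        geometric_mean=gmean,
        fold_assignment=fold_of,
        predictions=pred,
        seed=seed,
    )


def metrics(confusion: ArrayLike) -> tuple[float, float, float, float, float]:
    """(accuracy, macro recall, macro precision, F1, geometric mean of recalls)."""
    conf = np.asarray(confusion, dtype=np.int64)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = conf.sum()
    if total < 1 or (conf < 0).any():
        raise ValueError("confusion matrix must be nonnegative with >= 1 observation")
    tp = np.diag(conf).astype(float)
    row = conf.sum(axis=1).astype(float)  # truth counts (tp + fn)
    col = conf.sum(axis=0).astype(float)  # predicted counts (tp + fp)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, tp / row, 0.0)
        precision = np.where(col > 0, tp / col, 0.0)
    accuracy = float(tp.sum() / total)
    ar = float(recall.mean())
    ap = float(precision.mean())
    f1 = 0.0 if ap + ar == 0 else float(2.0 * ap * ar / (ap + ar))
    gmean = float(np.prod(recall) ** (1.0 / conf.shape[0]))
    return accuracy, ar, ap, f1, gmean
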