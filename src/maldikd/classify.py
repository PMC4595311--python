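"""Classifier evaluation over peak matrices.

The harness — not the classifiers — is the point here: it assigns samples
to cross-validation folds (stratified by default) or to a percentage
split, pools the held-out predictions, and computes all statistics from
the pooled confusion matrix: accuracy, Cohen's kappa, per-class precision
and recall, and a one-vs-rest ROC curve with AUC per condition.  The
classifier set is pluggable; adapters for naive Bayes, k-NN, decision
tree, random forest, SVM and a majority-vote dummy wrap scikit-learn
estimators exposing per-class scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ParameterError
from .matching import PeakMatrix

logger = logging.getLogger(__name__)


@dataclass
class EvaluationScheme:
    """How to split the data: k-fold cross-validation or a percentage split."""

    kind: str = "cross_validation"  # cross_validation | percentage_split
    folds: int = 10
    train_fraction: float = 0.66
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("cross_validation", "percentage_split"):
            raise ParameterError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "cross_validation" and self.folds < 2:
            raise ParameterError("cross-validation needs >= 2 folds")
        if self.kind == "percentage_split" and not 0 < self.train_fraction < 1:
            raise ParameterError("train fraction must lie in (0, 1)")


@dataclass
class ClassificationReport:
    """Pooled evaluation result."""

    labels: list[str]
    confusion: np.ndarray  # true x predicted counts
    accuracy: float
    kappa: float
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    roc: dict[str, dict]  # label -> {"points": [(fpr, tpr), ...], "auc": float}

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "confusion": self.confusion.astype(int).tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "precision": self.precision,
            "recall": self.recall,
            "roc": {
                k: {"points": [list(p) for p in v["points"]], "auc": v["auc"]}
                for k, v in self.roc.items()
            },
        }


CLASSIFIERS = ("naive_bayes", "knn", "decision_tree", "random_forest", "svm", "majority")


def make_classifier(name: str, seed: int = 0, **params):
    """Instantiate a scikit-learn estimator for one of the supported names."""
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "knn":
        params.setdefault("n_neighbors", 3)
        return KNeighborsClassifier(**params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if name == "svm":
        # per-class scores come from decision_function (one-vs-rest margins)
        return SVC(random_state=seed, **params)
    if name == "majority":
        return DummyClassifier(strategy="most_frequent")
    raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def compute_metrics(
    confusion: np.ndarray, labels: Sequence[str] | None = None
) -> tuple[float, float, dict[str, float | None], dict[str, float | None]]:
    """Accuracy, Cohen's kappa and per-class precision/recall from a
    true x predicted count matrix.

    Precision (recall) of a class with zero predicted (actual) instances
    is undefined and reported as ``None``.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ParameterError("confusion matrix must be square")
    if np.any(confusion < 0) or np.any(confusion != np.round(confusion)):
        raise ParameterError("confusion matrix must hold non-negative integer counts")
    total = confusion.sum()
    if total == 0:
        raise ParameterError("confusion matrix is all zero")
    k = confusion.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    p_o = float(np.trace(confusion)) / total
    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    p_e = float(np.dot(row, col)) / total ** 2
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0  # degenerate single-class margins
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for i, lab in enumerate(labels):
        precision[lab] = float(confusion[i, i] / col[i]) if col[i] > 0 else None
        recall[lab] = float(confusion[i, i] / row[i]) if row[i] > 0 else None
    return p_o, float(kappa), precision, recall


def roc_curve(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """One-vs-rest ROC by threshold sweep over the distinct scores.

    Returns the (FPR, TPR) points from (0,0) to (1,1) and the trapezoidal
    AUC.  Tied scores move along a single diagonal segment.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ParameterError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC needs both classes present in the truth vector")
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    sorted_scores = scores[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(sorted_scores):
        j = i
        while j < len(sorted_scores) and sorted_scores[j] == sorted_scores[i]:
            j += 1
        tp += int(sorted_truth[i:j].sum())
        fp += (j - i) - int(sorted_truth[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2
    return points, float(auc)


def _fold_indices(
    labels: np.ndarray, scheme: EvaluationScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    from sklearn.model_selection import (
        KFold,
        StratifiedKFold,
        train_test_split,
    )

    n = len(labels)
    if scheme.kind == "cross_validation":
        if scheme.folds > n:
            raise ParameterError(f"folds ({scheme.folds}) exceed sample count ({n})")
        if scheme.stratified:
            _, counts = np.unique(labels, return_counts=True)
            if counts.min() < scheme.folds:
                raise ParameterError(
                    "stratified CV needs every condition to have >= folds samples"
                )
            splitter = StratifiedKFold(
                n_splits=scheme.folds, shuffle=True, random_state=scheme.seed
            )
        else:
            splitter = KFold(n_splits=scheme.folds, shuffle=True, random_state=scheme.seed)
        return list(splitter.split(np.zeros(n), labels))
    idx = np.arange(n)
    train, test = train_test_split(
        idx,
        train_size=scheme.train_fraction,
        random_state=scheme.seed,
        stratify=labels if scheme.stratified else None,
    )
    return [(train, test)]


def evaluate(
    matrix: PeakMatrix,
    classifier: str = "naive_bayes",
    scheme: EvaluationScheme | None = None,
    **classifier_params,
) -> ClassificationReport:
    """Evaluate a classifier on a peak matrix and report pooled statistics.

    Folds (or the split) are assigned with the scheme's seed; held-out
    predictions and per-class scores are pooled across folds, the
    confusion matrix is built once over the pool, and all metrics plus
    per-condition one-vs-rest ROC curves derive from it.
    """
    scheme = scheme or EvaluationScheme()
    labels = np.asarray(matrix.conditions)
    classes = sorted(set(matrix.conditions))
    if len(classes) < 2:
        raise ParameterError("classification needs >= 2 conditions")
    x = matrix.values.astype(float)
    index_of = {c: i for i, c in enumerate(classes)}
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    pooled_scores = np.full((matrix.n_samples, len(classes)), np.nan)
    evaluated = np.zeros(matrix.n_samples, dtype=bool)
    for train, test in _fold_indices(labels, scheme):
        est = make_classifier(classifier, seed=scheme.seed, **classifier_params)
        train_labels = labels[train]
        if len(set(train_labels)) < len(classes):
            logger.warning(
                "fold training set misses %d condition(s); metrics cover available classes",
                len(classes) - len(set(train_labels)),
            )
        est.fit(x[train], train_labels)
        pred = est.predict(x[test])
        pooled_true.extend(labels[test])
        pooled_pred.extend(pred)
        evaluated[test] = True
        if hasattr(est, "predict_proba"):
            prob = est.predict_proba(x[test])
            for ci, cname in enumerate(est.classes_):
                pooled_scores[test, index_of[cname]] = prob[:, ci]
        elif hasattr(est, "decision_function"):
            dec = np.atleast_2d(est.decision_function(x[test]))
            if dec.shape[0] == 1 and len(est.classes_) == 2:
                dec = np.column_stack([-dec.ravel(), dec.ravel()])
            for ci, cname in enumerate(est.classes_):
                pooled_scores[test, index_of[cname]] = dec[:, ci]
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(pooled_true, pooled_pred):
        confusion[index_of[t], index_of[p]] += 1
    accuracy, kappa, precision, recall = compute_metrics(confusion, classes)
    roc: dict[str, dict] = {}
    for c in classes:
        col = pooled_scores[evaluated, index_of[c]]
        truth = (labels[evaluated] == c).astype(int)
        if np.any(np.isnan(col)):
            continue  # classifier exposed no scores
        try:
            points, auc = roc_curve(col, truth)
        except ParameterError:
            continue
        roc[c] = {"points": points, "auc": auc}
    return ClassificationReport(
        labels=classes,
        confusion=confusion,
        accuracy=accuracy,
        kappa=kappa,
        precision=precision,
        recall=recall,
        roc=roc,
    )
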