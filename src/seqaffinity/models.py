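"""Kernel models and evaluation protocols.

The classifier is a soft-margin SVM with a radial-basis kernel
K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2), penalty C; the regressor is
epsilon-insensitive support-vector regression with the same kernel.  Binary
metrics follow the usual confusion-count definitions: accuracy, sensitivity
(recall of the high-affinity class, the positive class), specificity, and the
Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when its denominator vanishes.  Cross-validation is
stratified; confusion counts are pooled over folds and metrics computed once
on the pooled counts.  Feature scaling is re-fit on each training fold and
applied to its test fold, so no test information leaks into the scaler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, SVR

from .encoding import HIGH, LOW, FeatureMatrix, apply_scaling, fit_scaling

#: the positive class for sensitivity/ROC purposes
POSITIVE_CLASS = HIGH


def binarize_labels(labels) -> np.ndarray:
    """Map {high, low} labels (or 0/1, or booleans) to a 0/1 integer vector
    with 1 = high affinity (the positive class)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return arr.astype(int)
    out = np.empty(arr.shape, dtype=int)
    for i, v in enumerate(arr.ravel()):
        if v in (HIGH, True, 1):
            out.ravel()[i] = 1
        elif v in (LOW, False, 0):
            out.ravel()[i] = 0
        else:
            raise ValueError(f"unrecognized class label {v!r}")
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        t = binarize_labels(y_true)
        p = binarize_labels(y_pred)
        return ConfusionCounts(
            tp=int(np.sum((t == 1) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fp=int(np.sum((t == 0) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )


@dataclass
class MetricsReport:
    confusion: ConfusionCounts
    accuracy: float      # percent
    sensitivity: float
    specificity: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.confusion.tp, "tn": self.confusion.tn,
            "fp": self.confusion.fp, "fn": self.confusion.fn,
            "accuracy_pct": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass
class RegressionReport:
    predictions: np.ndarray = field(repr=False)
    targets: np.ndarray = field(repr=False)
    pearson_r: float
    mae: float

    def to_dict(self) -> dict:
        return {"pearson_r": self.pearson_r, "mae": self.mae,
                "n": int(len(self.predictions))}


class TrainedClassifier:
    """Fitted RBF-SVM wrapper: class predictions plus a continuous decision
    score (distance to the separating hyperplane) for ROC analysis."""

    def __init__(self, svc: SVC):
        self._svc = svc

    def predict(self, X) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float))

    def decision_score(self, X) -> np.ndarray:
        return self._svc.decision_function(np.asarray(X, dtype=float))


def train_classifier(X, labels, c: float, gamma: float) -> TrainedClassifier:
    """Train the RBF-kernel SVM on feature rows ``X`` (already scaled)."""
    if isinstance(X, FeatureMatrix):
        X = X.values.to_numpy()
    y = binarize_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    svc = SVC(C=c, gamma=gamma, kernel="rbf")
    svc.fit(np.asarray(X, dtype=float), y)
    return TrainedClassifier(svc)


def compute_metrics(conf: ConfusionCounts) -> MetricsReport:
    """Accuracy/sensitivity/specificity/MCC from confusion counts.

    Accuracy is reported in percent.  An empty positive or negative margin
    (tp+fn == 0 or tn+fp == 0) leaves sensitivity or specificity undefined
    and raises; an MCC denominator of zero yields MCC = 0.
    """
    if conf.total == 0:
        raise ValueError("cannot compute metrics from zero evaluated complexes")
    if conf.tp + conf.fn == 0:
        raise ValueError("sensitivity undefined: no positive complexes evaluated")
    if conf.tn + conf.fp == 0:
        raise ValueError("specificity undefined: no negative complexes evaluated")
    accuracy = 100.0 * (conf.tp + conf.tn) / conf.total
    sensitivity = conf.tp / (conf.tp + conf.fn)
    specificity = conf.tn / (conf.tn + conf.fp)
    denom = math.sqrt(
        float(conf.tp + conf.fp) * (conf.tp + conf.fn)
        * (conf.tn + conf.fp) * (conf.tn + conf.fn)
    )
    mcc = 0.0 if denom == 0 else (conf.tp * conf.tn - conf.fp * conf.fn) / denom
    return MetricsReport(conf, accuracy, sensitivity, specificity, mcc)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counted half."""
    from sklearn.metrics import roc_auc_score

    y = binarize_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def stratified_folds(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold assignment (a pure function of
    seed and labels)."""
    y = binarize_labels(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold needs >= {k} members per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def cross_validate(
    matrix: FeatureMatrix, labels, k: int, c: float, gamma: float, seed: int
) -> MetricsReport:
    """Stratified k-fold CV of the RBF-SVM with per-fold scaling.

    Confusion counts and decision scores are pooled over folds; metrics
    (including AUC) are computed once on the pooled results.
    """
    y = binarize_labels(labels)
    X = matrix.values
    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    for train_idx, test_idx in stratified_folds(y, k, seed):
        train = fit_scaling(FeatureMatrix(X.iloc[train_idx]))
        test = apply_scaling(FeatureMatrix(X.iloc[test_idx]), train.scaling)
        clf = train_classifier(train.values.to_numpy(), y[train_idx], c, gamma)
        preds[test_idx] = clf.predict(test.values.to_numpy())
        scores[test_idx] = clf.decision_score(test.values.to_numpy())
    report = compute_metrics(ConfusionCounts.from_predictions(y, preds))
    report.auc = roc_auc(scores, y)
    return report


def jackknife_regress(
    matrix: FeatureMatrix, pkd, c: float, gamma: float, epsilon: float = 0.1
) -> RegressionReport:
    """Leave-one-out SVR estimation of pKd.

    Each complex is predicted by a regressor trained on the remaining n-1
    (scaling re-fit on each training set).  Reports the Pearson correlation
    and mean absolute error of the held-out predictions; if the predictions
    are constant the correlation is undefined and reported as NaN.
    """
    t = np.asarray(pkd, dtype=float)
    n = len(t)
    if n < 3:
        raise ValueError("jackknife regression needs at least 3 complexes")
    X = matrix.values
    preds = np.empty(n)
    for i in range(n):
        rest = np.r_[0:i, i + 1:n]
        train = fit_scaling(FeatureMatrix(X.iloc[rest]))
        test = apply_scaling(FeatureMatrix(X.iloc[[i]]), train.scaling)
        svr = SVR(C=c, gamma=gamma, epsilon=epsilon, kernel="rbf")
        svr.fit(train.values.to_numpy(), t[rest])
        preds[i] = svr.predict(test.values.to_numpy())[0]
    mae = float(np.mean(np.abs(preds - t)))
    if np.ptp(preds) == 0 or np.ptp(t) == 0:
        warnings.warn("constant predictions or targets: Pearson r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(preds, t).statistic)
    return RegressionReport(preds, t, r, mae)


def holdout_split(labels, test_fraction: float = 0.25, seed: int = 0):
    """Seeded stratified holdout split; returns (train_idx, test_idx).

    With 216 balanced complexes and the default 25% test fraction this gives
    the 162/54 partition (81/27 per class).
    """
    from sklearn.model_selection import train_test_split

    y = binarize_labels(labels)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    return np.sort(train_idx), np.sort(test_idx)
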