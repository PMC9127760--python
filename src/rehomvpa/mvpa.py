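"""Multivariate pattern classification of smoothed ReHo maps.

Feature assembly (subjects x in-mask voxels), fold-wise mean centering,
linear SVM and Gaussian-process classifiers, leave-one-subject-out
cross-validation (LOSOCV), and the full performance-metric set
(sensitivity, specificity, PPV, NPV, balanced/total accuracy, AUC).

All classifiers are linear, so each trained model carries an explicit
weight vector: the decision function is f(x) = w0 + w.x, and the per-fold
weight vectors are retained for discriminative-map construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .gpc import LaplaceGPC
from .types import ReHoMap

__all__ = [
    "FeatureMatrix",
    "LinearModel",
    "CVResult",
    "build_features",
    "features_to_map",
    "mean_center",
    "fit_linear_svm",
    "fit_gpc",
    "losocv",
    "performance_metrics",
    "rank_auc",
    "pairwise_auc",
]

ALGORITHMS = ("svm", "bgpc", "mgpc")


@dataclass
class FeatureMatrix:
    """Subjects x voxels feature matrix with the column -> grid mapping.

    ``voxel_index[j]`` is the (i, j, k) grid coordinate of column ``j``;
    columns follow lexicographic (C) order of the in-mask coordinates.
    """

    values: np.ndarray
    voxel_index: np.ndarray  # (n_voxels, 3) int
    subject_ids: list[str]
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2D (subjects x voxels)")
        if self.voxel_index.shape != (self.values.shape[1], 3):
            raise ValueError(
                f"voxel_index shape {self.voxel_index.shape} inconsistent with "
                f"{self.values.shape[1]} columns"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        ids = [self.subject_ids[i] for i in np.atleast_1d(rows)]
        return FeatureMatrix(self.values[rows], self.voxel_index, ids, self.grid_shape)


def build_features(maps: list[ReHoMap], mask: np.ndarray) -> FeatureMatrix:
    """Stack per-subject map values at in-mask voxels into a feature matrix."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)  # lexicographic order
    rows = []
    ids = []
    for m in maps:
        if m.values.shape != mask.shape:
            raise ValueError(
                f"map grid {m.values.shape} != mask grid {mask.shape} "
                f"(subject {m.subject_id!r})"
            )
        rows.append(m.values[mask])
        ids.append(m.subject_id)
    return FeatureMatrix(np.vstack(rows), coords, ids, grid_shape=tuple(mask.shape))


def features_to_map(
    vector: np.ndarray, voxel_index: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Scatter a per-voxel feature/weight vector back onto the 3D grid."""
    out = np.zeros(grid_shape, dtype=np.float64)
    out[tuple(np.asarray(voxel_index).T)] = vector
    return out


def mean_center(
    train: FeatureMatrix, test: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Subtract training-column means from both sets (no test leakage)."""
    if train.n_voxels != test.n_voxels:
        raise ValueError("train/test column counts differ")
    mu = train.values.mean(axis=0)
    return (
        FeatureMatrix(train.values - mu, train.voxel_index, train.subject_ids, train.grid_shape),
        FeatureMatrix(test.values - mu, test.voxel_index, test.subject_ids, test.grid_shape),
    )


@dataclass
class LinearModel:
    """A linear decision rule f(x) = w0 + w.x over voxel features."""

    weights: np.ndarray  # (V,) binary, (C, V) multiclass
    bias: float | np.ndarray
    classes: np.ndarray
    algorithm: str
    model: object = None

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """Binary: signed score toward classes[1].  Multiclass: (m, C) scores."""
        x = np.asarray(x, dtype=np.float64)
        if self.weights.ndim == 1:
            return self.bias + x @ self.weights
        return (self.weights @ x.T).T + np.asarray(self.bias)[None, :]

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision_values(x)
        if self.weights.ndim == 1:
            return np.where(scores >= 0, self.classes[1], self.classes[0])
        return self.classes[np.argmax(scores, axis=1)]

    def predict_proba(self, x: np.ndarray) -> np.ndarray | None:
        if isinstance(self.model, LaplaceGPC):
            return self.model.predict_proba(np.asarray(x, dtype=np.float64))
        return None


def fit_linear_svm(x: np.ndarray, y: np.ndarray, c_param: float = 1.0) -> LinearModel:
    """Soft-margin linear support vector machine (C-SVC)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if len(classes) > 2:
        raise ValueError("linear SVM here is binary; use mgpc for 3 classes")
    svc = SVC(kernel="linear", C=c_param)
    svc.fit(np.asarray(x, dtype=np.float64), y)
    return LinearModel(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        classes=svc.classes_,
        algorithm="svm",
        model=svc,
    )


def fit_gpc(x: np.ndarray, y: np.ndarray, mode: str = "binary", sigma0_sq: float = 10.0) -> LinearModel:
    """Laplace-approximate Gaussian-process classifier, linear kernel.

    ``mode="binary"`` uses the logistic likelihood; ``mode="multiclass"``
    the softmax likelihood (requires >= 3 classes in ``y``; with 2 it
    degrades gracefully to the binary model).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if mode not in ("binary", "multiclass"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "binary" and len(classes) > 2:
        raise ValueError("binary GPC got more than 2 classes; use mode='multiclass'")
    gpc = LaplaceGPC(sigma0_sq=sigma0_sq)
    gpc.fit(np.asarray(x, dtype=np.float64), y)
    return LinearModel(
        weights=np.asarray(gpc.weights_),
        bias=gpc.bias_,
        classes=gpc.classes_,
        algorithm="bgpc" if not gpc.multiclass_ else "mgpc",
        model=gpc,
    )


def _fit(algorithm: str, x: np.ndarray, y: np.ndarray, c_param: float, sigma0_sq: float) -> LinearModel:
    if algorithm == "svm":
        return fit_linear_svm(x, y, c_param=c_param)
    if algorithm == "bgpc":
        return fit_gpc(x, y, mode="binary", sigma0_sq=sigma0_sq)
    if algorithm == "mgpc":
        mode = "multiclass" if len(np.unique(y)) > 2 else "binary"
        return fit_gpc(x, y, mode=mode, sigma0_sq=sigma0_sq)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


@dataclass
class CVResult:
    """Held-out predictions and derived metrics of one LOSOCV run."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # binary: (n,) decision values; multiclass: (n, C) probs
    classes: np.ndarray
    positive_class: str | None
    algorithm: str
    confusion: np.ndarray = field(init=False)
    metrics: dict = field(init=False)
    fold_weights: np.ndarray | None = None  # (n_folds, V) for binary models

    def __post_init__(self) -> None:
        idx = {c: i for i, c in enumerate(self.classes)}
        self.confusion = np.zeros((len(self.classes), len(self.classes)), dtype=int)
        for t, p in zip(self.y_true, self.y_pred):
            self.confusion[idx[t], idx[p]] += 1
        self.metrics = performance_metrics(
            self.confusion,
            classes=self.classes,
            positive=self.positive_class,
            scores=self.scores if self.scores.ndim == 1 else None,
            y_true=self.y_true,
        )

    @property
    def mean_weights(self) -> np.ndarray | None:
        if self.fold_weights is None:
            return None
        return self.fold_weights.mean(axis=0)


def losocv(
    features: FeatureMatrix,
    labels: np.ndarray,
    algorithm: str = "svm",
    c_param: float = 1.0,
    sigma0_sq: float = 10.0,
    positive_class: str | None = None,
    center: str = "fold",
) -> CVResult:
    """Leave-one-subject-out cross-validation.

    Each of the n folds trains on n-1 subjects (features mean-centered with
    training-fold statistics only, unless ``center="global"``) and predicts
    the held-out subject; the n held-out predictions form the confusion
    matrix.  Deterministic: no stochastic step is involved.
    """
    labels = np.asarray(labels)
    n = features.n_subjects
    if len(labels) != n:
        raise ValueError("label count != subject count")
    if n < 3:
        raise ValueError("LOSOCV needs at least 3 subjects")
    if center not in ("fold", "global"):
        raise ValueError(f"unknown centering {center!r}")
    classes = np.unique(labels)
    if positive_class is None:
        positive_class = str(classes[0])  # patient class sorts first (DET < ET < HC)
    elif positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among labels")

    binary = len(classes) == 2
    y_pred = np.empty(n, dtype=labels.dtype)
    scores = np.zeros(n) if binary else np.zeros((n, len(classes)))
    fold_w = np.zeros((n, features.n_voxels)) if binary else None

    if center == "global":
        mu = features.values.mean(axis=0)

    for k in range(n):
        train_rows = np.setdiff1d(np.arange(n), [k])
        y_train = labels[train_rows]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {k} contains a single class")
        x_train = features.values[train_rows]
        x_test = features.values[k : k + 1]
        if center == "fold":
            mu = x_train.mean(axis=0)
        x_train = x_train - mu
        x_test = x_test - mu
        model = _fit(algorithm, x_train, y_train, c_param, sigma0_sq)
        y_pred[k] = model.predict(x_test)[0]
        if binary:
            dv = float(np.ravel(model.decision_values(x_test))[0])
            w = model.weights if model.weights.ndim == 1 else model.weights[0]
            # orient score and weights so larger means "more like the
            # positive (patient) class": positive map weight = patient > control
            if model.classes[1] != positive_class:
                dv = -dv
                w = -w
            scores[k] = dv
            fold_w[k] = w
        else:
            proba = model.predict_proba(x_test)
            scores[k] = proba[0] if proba is not None else np.nan

    return CVResult(
        subject_ids=list(features.subject_ids),
        y_true=labels,
        y_pred=y_pred,
        scores=scores,
        classes=classes,
        positive_class=positive_class,
        algorithm=algorithm,
        fold_weights=fold_w,
    )


def rank_auc(y_true: np.ndarray, scores: np.ndarray, positive) -> float:
    """AUC via the Mann-Whitney rank statistic (ties count 1/2)."""
    y_true = np.asarray(y_true)
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: one class absent", stacklevel=2)
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pairwise_auc(
    y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray
) -> dict[tuple[str, str], float]:
    """One-vs-one AUCs from a multiclass probability matrix."""
    y_true = np.asarray(y_true)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(classes):
        for j, b in enumerate(classes):
            if j <= i:
                continue
            sel = (y_true == a) | (y_true == b)
            denom = proba[sel, i] + proba[sel, j]
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(denom > 0, proba[sel, i] / denom, 0.5)
            out[(str(a), str(b))] = rank_auc(y_true[sel], score, a)
    return out


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def performance_metrics(
    confusion: np.ndarray,
    classes: np.ndarray | None = None,
    positive=None,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> dict:
    """Classification metrics from a (true x predicted) confusion matrix.

    Binary: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
    NPV TN/(TN+FN), balanced accuracy (sens+spec)/2, total accuracy
    trace/sum, plus rank-based AUC when held-out scores are supplied.
    Multiclass: per-class sensitivity, total and balanced accuracy.
    All values are fractions in [0, 1]; zero-denominator metrics are NaN.
    """
    confusion = np.asarray(confusion)
    if confusion.size == 0 or confusion.sum() == 0:
        raise ValueError("empty confusion matrix")
    n_classes = confusion.shape[0]
    if classes is None:
        classes = np.arange(n_classes)
    total = float(confusion.sum())
    metrics: dict = {"total_accuracy": float(np.trace(confusion)) / total}

    if n_classes == 2:
        if positive is None:
            positive = classes[0]
        p = int(np.where(np.asarray(classes) == positive)[0][0])
        q = 1 - p
        tp, fn = confusion[p, p], confusion[p, q]
        fp, tn = confusion[q, p], confusion[q, q]
        sens = _safe_div(tp, tp + fn, "sensitivity")
        spec = _safe_div(tn, tn + fp, "specificity")
        metrics.update(
            sensitivity=sens,
            specificity=spec,
            ppv=_safe_div(tp, tp + fp, "PPV"),
            npv=_safe_div(tn, tn + fn, "NPV"),
            balanced_accuracy=(sens + spec) / 2.0,
            positive_class=str(positive),
        )
        if scores is not None and y_true is not None:
            metrics["auc"] = rank_auc(y_true, scores, positive)
    else:
        per_class = {}
        for i, c in enumerate(classes):
            per_class[str(c)] = _safe_div(
                confusion[i, i], confusion[i].sum(), f"sensitivity[{c}]"
            )
        metrics["per_class_sensitivity"] = per_class
        vals = [v for v in per_class.values() if not np.isnan(v)]
        metrics["balanced_accuracy"] = float(np.mean(vals)) if vals else float("nan")
    return metrics
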