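"""SVM classification of CTG feature rows and the confusion-matrix metric suite.

A binary support vector machine separates normal from suspicious traces
using six inputs (bradycardia and tachycardia episode counts, acceleration
and deceleration counts, STV, SVB).  Three kernels are supported (linear,
second-order polynomial, RBF) and the model is evaluated by stratified
k-fold cross-validation (10 folds by default): each sample is predicted
exactly once by a model that never saw it, feature standardisation is fitted
on the training folds only.

The metric suite is computed from the confusion matrix with the *normal*
class as positive:

    accuracy    = (TP+TN)/(TP+FP+TN+FN)        sensitivity = TP/(TP+FN)
    specificity = TN/(TN+FP)                    precision   = TP/(TP+FP)
    F_beta      = (1+b^2)*P*S / (b^2*P + S)     G-mean      = sqrt(sens*spec)

Rates are reported as percentages; F_beta stays on [0, 1].  Per-class values
are obtained by swapping the positive class, and overall rows aggregate the
two classes by arithmetic mean and by class-size-weighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ContractError

KERNELS = ("linear", "polynomial_degree2", "rbf")

METRIC_KEYS = (
    "accuracy",
    "misclassification_error",
    "sensitivity",
    "specificity",
    "precision",
    "f_beta",
    "g_mean",
)


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "rbf"
    regularization: float = 1.0
    kernel_scale: float | str = "scale"
    standardize: bool = True
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def make_estimator(self):
        if self.kernel == "linear":
            svc = SVC(kernel="linear", C=self.regularization)
        elif self.kernel == "polynomial_degree2":
            svc = SVC(
                kernel="poly", degree=2, C=self.regularization, gamma=self.kernel_scale
            )
        elif self.kernel == "rbf":
            svc = SVC(kernel="rbf", C=self.regularization, gamma=self.kernel_scale)
        else:
            raise ContractError(f"unknown kernel {self.kernel!r}")
        if self.standardize:
            return make_pipeline(StandardScaler(), svc)
        return svc


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    positive_class: str = "normal"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ContractError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def swapped(self, other_class: str) -> "ConfusionMatrix":
        """The same predictions with the other class treated as positive."""
        return ConfusionMatrix(
            tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp, positive_class=other_class
        )

    @classmethod
    def from_labels(cls, y_true, y_pred, positive_class: str = "normal"):
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_class
        pos_p = y_pred == positive_class
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            positive_class=positive_class,
        )


def _ratio(num: float, den: float) -> float:
    """Percentage ratio; NaN marks an undefined (0/0) metric."""
    return float("nan") if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix, beta: float = 1.0) -> dict[str, float]:
    """Metric set for one positive class; percentages except ``f_beta``."""
    if cm.total == 0:
        raise ContractError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    b2 = beta * beta
    if math.isnan(prec) or math.isnan(sens) or (b2 * prec + sens) == 0:
        fb = float("nan")
    else:
        fb = (1 + b2) * (prec / 100.0) * (sens / 100.0) / (
            b2 * prec / 100.0 + sens / 100.0
        )
    return {
        "accuracy": acc,
        "misclassification_error": 100.0 - acc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_beta": fb,
        "g_mean": g_mean(sens, spec),
    }


def g_mean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity (both in %)."""
    if math.isnan(sensitivity) or math.isnan(specificity):
        return float("nan")
    return math.sqrt(sensitivity * specificity)


def aggregate_metrics(
    per_class: dict[str, dict[str, float]], class_sizes: dict[str, int]
) -> dict[str, dict[str, float]]:
    """Arithmetic and class-size-weighted means of per-class metric rows."""
    classes = list(per_class)
    if len(classes) != 2 or any(class_sizes[c] <= 0 for c in classes):
        raise ContractError("need two classes with positive sizes")
    total = sum(class_sizes.values())
    arith: dict[str, float] = {}
    weighted: dict[str, float] = {}
    for key in METRIC_KEYS:
        vals = [per_class[c][key] for c in classes]
        wts = [class_sizes[c] / total for c in classes]
        arith[key] = float(np.mean(vals))
        weighted[key] = float(sum(v * w for v, w in zip(vals, wts)))
    return {"arithmetic": arith, "weighted": weighted}


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metrics plus the two overall aggregation rows."""

    per_class: dict[str, dict[str, float]]
    overall_arithmetic: dict[str, float]
    overall_weighted: dict[str, float]
    confusion: ConfusionMatrix
    beta: float = 1.0

    @classmethod
    def from_confusion(
        cls, cm: ConfusionMatrix, negative_class: str = "suspicious", beta: float = 1.0
    ) -> "MetricsReport":
        per_class = {
            cm.positive_class: compute_metrics(cm, beta=beta),
            negative_class: compute_metrics(cm.swapped(negative_class), beta=beta),
        }
        sizes = {cm.positive_class: cm.n_positive, negative_class: cm.n_negative}
        agg = aggregate_metrics(per_class, sizes)
        return cls(
            per_class=per_class,
            overall_arithmetic=agg["arithmetic"],
            overall_weighted=agg["weighted"],
            confusion=cm,
            beta=beta,
        )

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "positive_class": self.confusion.positive_class,
            },
            "per_class": self.per_class,
            "overall_arithmetic": self.overall_arithmetic,
            "overall_weighted": self.overall_weighted,
        }


@dataclass(frozen=True)
class CVResult:
    predictions: np.ndarray
    fold_of_sample: np.ndarray
    pooled_confusion: ConfusionMatrix
    pooled_report: MetricsReport
    fold_metrics: list[dict[str, float]]
    fold_mean: dict[str, float]


def cross_validate(
    features: np.ndarray,
    labels,
    config: ClassifierConfig | None = None,
    positive_class: str = "normal",
    negative_class: str = "suspicious",
) -> CVResult:
    """k-fold cross-validation of the SVM on a feature matrix.

    Every sample is predicted exactly once; the pooled confusion matrix over
    all held-out predictions is the primary report, with per-fold metric
    means reported alongside.  Reproducible for a fixed config seed.
    """
    config = config or ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ContractError("features must be (n_samples, n_features) matching labels")
    n = y.size
    if len(np.unique(y)) < 2:
        raise ContractError("both classes must be present")
    if not 2 <= config.n_folds <= n:
        raise ContractError("n_folds must be between 2 and the number of samples")

    min_class = min(np.sum(y == c) for c in np.unique(y))
    if config.stratified and config.n_folds <= min_class:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X, y)
    else:  # leave-one-out-like regimes cannot stratify
        splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        splits = splitter.split(X)

    preds = np.empty(n, dtype=y.dtype)
    fold_of = np.full(n, -1, dtype=int)
    fold_metrics: list[dict[str, float]] = []
    for k, (tr, te) in enumerate(splits):
        est = config.make_estimator()
        est.fit(X[tr], y[tr])
        p = est.predict(X[te])
        preds[te] = p
        fold_of[te] = k
        cm_k = ConfusionMatrix.from_labels(y[te], p, positive_class)
        if cm_k.total:
            fold_metrics.append(compute_metrics(cm_k))
    assert (fold_of >= 0).all(), "every sample must be tested exactly once"

    pooled = ConfusionMatrix.from_labels(y, preds, positive_class)
    report = MetricsReport.from_confusion(pooled, negative_class=negative_class)
    fold_mean = {}
    for key in METRIC_KEYS:
        vals = [m[key] for m in fold_metrics if not math.isnan(m[key])]
        fold_mean[key] = float(np.mean(vals)) if vals else float("nan")
    return CVResult(
        predictions=preds,
        fold_of_sample=fold_of,
        pooled_confusion=pooled,
        pooled_report=report,
        fold_metrics=fold_metrics,
        fold_mean=fold_mean,
    )
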