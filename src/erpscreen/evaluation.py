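"""Seven-model registry, cross-validation, and performance metrics.

The classifier families and their hyperparameters are fixed by the study
design this pipeline follows: a linear ("dot"-kernel) SVM, a 50-layer
rectifier network, an unpenalized binomial GLM thresholded at 0.5, ridge
logistic regression, a depth-20 decision tree, a 100-tree depth-10 random
forest (both with information-theoretic splits), and Gaussian naive
Bayes.  All internals are delegated to scikit-learn; this module owns the
cross-validation protocol, confusion-matrix metrics and ROC/AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedGroupKFold,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, KEY_COLUMNS, LABEL_COLUMN

__all__ = [
    "MODEL_NAMES",
    "CVSpec",
    "ConfusionMatrix",
    "Metrics",
    "EvalResult",
    "make_model",
    "make_models",
    "make_folds",
    "cross_validate",
    "metrics",
    "roc_auc",
]

MODEL_NAMES = ("NB", "GLM", "LR", "DL", "DT", "RF", "SVM")

POSITIVE_CLASS = "ADHD"


def make_model(
    name: str,
    seed: int = 0,
    dl_width: int = 16,
    dl_max_iter: int = 200,
):
    """Instantiate one configured classifier by registry name.

    Scale-sensitive estimators (SVM, the deep network, the two
    regressions) are wrapped with a within-fold standardizer; tree models
    and naive Bayes are scale-invariant and run on raw features.
    """
    if name == "NB":
        # Gaussian event model for continuous features; the Laplace count
        # correction of categorical naive Bayes has no analogue here.
        return GaussianNB()
    if name == "GLM":
        # Unpenalized binomial GLM with logit link, decision threshold 0.5.
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(penalty=None, max_iter=500),
        )
    if name == "LR":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=500),
        )
    if name == "DL":
        # 50 hidden rectifier layers; width is a free parameter.
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(dl_width,) * 50,
                activation="relu",
                max_iter=dl_max_iter,
                random_state=seed,
            ),
        )
    if name == "DT":
        # Entropy splits stand in for the gain-ratio criterion.
        return DecisionTreeClassifier(
            max_depth=20, criterion="entropy", random_state=seed
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=100, max_depth=10, criterion="entropy", random_state=seed
        )
    if name == "SVM":
        return make_pipeline(StandardScaler(), SVC(kernel="linear"))
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def make_models(seed: int = 0, names=MODEL_NAMES, **kwargs) -> dict:
    return {name: make_model(name, seed=seed, **kwargs) for name in names}


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation protocol.

    ``grouped=True`` keeps all records of a subject in one fold
    (leakage-free default); ``grouped=False`` reproduces record-level
    folding in which a subject's records may straddle train and test.
    ``mode="holdout"`` replaces K-fold with a single stratified
    train/test split of ``train_fraction``.
    """

    n_folds: int = 10
    grouped: bool = True
    seed: int = 0
    mode: str = "kfold"  # "kfold" | "holdout"
    train_fraction: float = 0.7


def make_folds(
    labels: np.ndarray, groups: np.ndarray, cv_spec: CVSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialize fold index pairs once, so every model and every
    candidate pattern is compared on identical partitions."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if cv_spec.mode == "holdout":
        if cv_spec.grouped:
            splitter = GroupShuffleSplit(
                n_splits=1,
                train_size=cv_spec.train_fraction,
                random_state=cv_spec.seed,
            )
        else:
            splitter = StratifiedShuffleSplit(
                n_splits=1,
                train_size=cv_spec.train_fraction,
                random_state=cv_spec.seed,
            )
    elif cv_spec.mode == "kfold":
        cls = StratifiedGroupKFold if cv_spec.grouped else StratifiedKFold
        splitter = cls(
            n_splits=cv_spec.n_folds, shuffle=True, random_state=cv_spec.seed
        )
    else:
        raise ValueError(f"unknown cv mode {cv_spec.mode!r}")
    g = groups if cv_spec.grouped else None
    return [
        (np.asarray(tr), np.asarray(te))
        for tr, te in splitter.split(np.zeros(len(labels)), labels, g)
    ]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix summary; ratios with a zero denominator are
    reported as None, never as 0."""

    accuracy: float  # %
    precision: float | None  # %
    classification_error: float  # %
    sensitivity: float | None
    specificity: float | None


def metrics(cm: ConfusionMatrix) -> Metrics:
    total = cm.total
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / total
    precision = 100.0 * cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    error = 100.0 * (cm.fp + cm.fn) / total
    sensitivity = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    specificity = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return Metrics(accuracy, precision, error, sensitivity, specificity)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep, and trapezoidal AUC.

    ``labels`` are booleans or 0/1 with 1 = positive class.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class EvalResult:
    """Pooled out-of-fold performance of one (model, band, pattern)."""

    model_name: str
    band: str
    features: tuple[str, ...]
    confusion: ConfusionMatrix
    metrics: Metrics
    roc_points: np.ndarray
    auc: float
    cv_spec: CVSpec
    fold_accuracies: list[float] = field(default_factory=list)


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        classes = list(estimator.classes_)
        sc = estimator.predict_proba(X)[:, classes.index(POSITIVE_CLASS)]
    else:
        sc = estimator.decision_function(X)
        if list(estimator.classes_)[1] != POSITIVE_CLASS:
            sc = -sc
    # a zero-variance feature can defeat a Gaussian likelihood model;
    # treat undefined scores as uninformative rather than failing the cell
    return np.nan_to_num(sc, nan=0.0, posinf=0.0, neginf=0.0)


def cross_validate(
    model,
    table: pd.DataFrame,
    features,
    cv_spec: CVSpec = CVSpec(),
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    band: str = "",
    model_name: str = "",
) -> EvalResult:
    """Cross-validate one classifier on one feature pattern.

    Out-of-fold predictions are pooled into a single confusion matrix
    (positive class = ADHD); decision scores are retained for the ROC.
    ``folds`` may be supplied to share one partition across many calls.
    """
    features = tuple(features)
    unknown = [f for f in features if f not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s) {unknown}")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy()
    groups = table[KEY_COLUMNS[0]].to_numpy()
    if folds is None:
        folds = make_folds(y, groups, cv_spec)
    y_true = np.empty(0, dtype=bool)
    y_pred = np.empty(0, dtype=bool)
    scores = np.empty(0, dtype=float)
    fold_accuracies = []
    for k, (train, test) in enumerate(folds):
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {k}: a class is absent from the training split")
        est = clone(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train], y[train])
            pred = est.predict(X[test]) == POSITIVE_CLASS
            sc = _scores(est, X[test])
        truth = y[test] == POSITIVE_CLASS
        y_true = np.concatenate([y_true, truth])
        y_pred = np.concatenate([y_pred, pred])
        scores = np.concatenate([scores, sc])
        fold_accuracies.append(float(np.mean(pred == truth)) * 100.0)
    cm = ConfusionMatrix(
        tp=int(np.sum(y_pred & y_true)),
        tn=int(np.sum(~y_pred & ~y_true)),
        fp=int(np.sum(y_pred & ~y_true)),
        fn=int(np.sum(~y_pred & y_true)),
    )
    if len(np.unique(y_true)) == 2:
        roc_points, auc = roc_auc(scores, y_true)
    else:  # degenerate test pool
        roc_points, auc = np.zeros((0, 2)), float("nan")
    return EvalResult(
        model_name=model_name,
        band=band,
        features=features,
        confusion=cm,
        metrics=metrics(cm),
        roc_points=roc_points,
        auc=auc,
        cv_spec=cv_spec,
        fold_accuracies=fold_accuracies,
    )
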