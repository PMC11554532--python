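"""Shallow neural-network classifiers, the metric suite, and the
classifier-comparison t-test.

Five fully connected classifier families are used downstream of feature
fusion — narrow (10), medium (25), wide (100), bilayered (10, 10) and
trilayered (10, 10, 10) hidden units, ReLU hidden activation, softmax
output — matching the MATLAB Classification Learner presets the study
environment implies.  Metrics are reported on the 0-100 scale
(accuracy, macro precision/recall/F1, FNR = 100 - macro recall) with
macro one-vs-rest AUC, generalized (Gorodkin) multiclass Matthews
correlation and Cohen's kappa, all derived from pooled predictions.

The comparison t-test works on per-experiment accuracy differences
``d_i = |acc_high_i - acc_low_i|``: with mean ``mu`` and sample SD
``sigma`` (N - 1 denominator), ``t = sqrt(N) * mu / sigma`` is compared
against the two-tailed Student critical interval at ``alpha`` with
``N - 1`` degrees of freedom.  ``mu`` and ``sigma`` are rounded to 4
decimals before forming the reported ``t`` (reproducing the published
arithmetic); the full-precision value is reported alongside.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .train_extract import DataError, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILY_LAYOUTS",
    "ClassifierSpec",
    "MetricsReport",
    "TTestReport",
    "ShallowNeuralNetClassifier",
    "train_shallow_nn",
    "evaluate",
    "kfold_cv",
    "paired_diff_ttest",
    "critical_t",
]

FAMILY_LAYOUTS = {
    "narrow": (10,),
    "medium": (25,),
    "wide": (100,),
    "bilayered": (10, 10),
    "trilayered": (10, 10, 10),
}


@dataclass
class ClassifierSpec:
    """One shallow NN family; ``hidden`` defaults to the family layout."""

    family: str = "narrow"
    hidden: tuple[int, ...] | None = None
    activation: str = "relu"
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LAYOUTS:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {sorted(FAMILY_LAYOUTS)}"
            )
        if self.hidden is None:
            self.hidden = FAMILY_LAYOUTS[self.family]
        elif tuple(self.hidden) != FAMILY_LAYOUTS[self.family]:
            raise ValueError(
                f"hidden layout {self.hidden} does not match family {self.family!r}"
            )


class ShallowNeuralNetClassifier:
    """sklearn-style classifier wrapping a fully connected net.

    Features are standardized inside the estimator; the underlying MLP
    trains with L-BFGS (deterministic under ``seed`` for these small
    problems).  Fitted attributes: ``classes_``, ``n_hidden_layers_``.
    """

    def __init__(self, family: str = "narrow", max_iter: int = 400, seed: int = 0):
        self.family = family
        self.max_iter = max_iter
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"family": self.family, "max_iter": self.max_iter, "seed": self.seed}

    def set_params(self, **params) -> "ShallowNeuralNetClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShallowNeuralNetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise DataError("features contain non-finite values")
        if len(np.unique(y)) < 2:
            raise DataError("training requires at least 2 classes")
        spec = ClassifierSpec(family=self.family, max_iter=self.max_iter, seed=self.seed)
        self._scaler = StandardScaler().fit(X)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=spec.hidden,
            activation=spec.activation,
            solver="lbfgs",
            max_iter=spec.max_iter,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._mlp.fit(self._scaler.transform(X), y)
        self.classes_ = self._mlp.classes_
        self.n_hidden_layers_ = len(spec.hidden)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._mlp.predict(self._scaler.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._mlp.predict_proba(self._scaler.transform(np.asarray(X, dtype=float)))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_shallow_nn(spec: ClassifierSpec, X: FeatureMatrix) -> ShallowNeuralNetClassifier:
    """Fit one shallow NN family on a feature matrix."""
    clf = ShallowNeuralNetClassifier(
        family=spec.family, max_iter=spec.max_iter, seed=spec.seed
    )
    return clf.fit(X.values, X.labels)


@dataclass
class MetricsReport:
    """Evaluation quantities on the reporting scale (percent)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    fnr: float
    mcc: float
    kappa: float
    confusion: np.ndarray

    def to_json(self, path: str | Path) -> None:
        doc = {k: v for k, v in asdict(self).items() if k != "confusion"}
        doc["confusion"] = np.asarray(self.confusion).tolist()
        Path(path).write_text(json.dumps(doc, indent=1))

    def confusion_to_csv(self, path: str | Path, class_names: list[str] | None = None) -> None:
        cm = np.asarray(self.confusion)
        names = class_names or [str(i) for i in range(len(cm))]
        pd.DataFrame(cm, index=names, columns=names).to_csv(path)


def _metrics_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray | None,
    classes: np.ndarray,
) -> MetricsReport:
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum()) * 100.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        )
    if (cm.sum(axis=0) == 0).any():
        logger.info("a class has no predicted instances; its precision counts as 0")
    if y_score is not None and len(classes) > 1:
        try:
            if len(classes) == 2:
                auc = float(roc_auc_score(y_true, y_score[:, 1]))
            else:
                auc = float(
                    roc_auc_score(
                        y_true, y_score, multi_class="ovr", average="macro", labels=classes
                    )
                )
        except ValueError:  # a class absent from y_true
            auc = float("nan")
    else:
        auc = float("nan")
    return MetricsReport(
        accuracy=accuracy,
        precision=float(precision) * 100.0,
        recall=float(recall) * 100.0,
        f1=float(f1) * 100.0,
        auc=auc,
        fnr=100.0 - float(recall) * 100.0,
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        kappa=float(cohen_kappa_score(y_true, y_pred)),
        confusion=cm,
    )


def evaluate(classifier, X: FeatureMatrix) -> MetricsReport:
    """Score a fitted classifier on a labeled feature matrix."""
    y_pred = classifier.predict(X.values)
    y_score = (
        classifier.predict_proba(X.values) if hasattr(classifier, "predict_proba") else None
    )
    classes = getattr(classifier, "classes_", np.unique(X.labels))
    return _metrics_from_predictions(X.labels, y_pred, y_score, np.asarray(classes))


def kfold_cv(
    spec: ClassifierSpec, X: FeatureMatrix, k: int = 10, seed: int = 0
) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled scoring.

    Out-of-fold predictions from all folds are pooled and scored once.
    ``k`` is reduced (with a warning) when the smallest class has fewer
    than ``k`` members; fewer than 2 samples per class is an error.
    """

    y = X.labels
    n = len(y)
    if k > n:
        raise DataError(f"k={k} exceeds the number of samples ({n})")
    min_class = int(np.bincount(y).min()) if y.size else 0
    classes = np.unique(y)
    if min_class < 2:
        raise DataError("every class needs at least 2 members for cross-validation")
    if min_class < k:
        logger.warning("reducing k from %d to %d (smallest class size)", k, min_class)
        k = min_class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(n, dtype=y.dtype)
    y_score = np.zeros((n, len(classes)))
    for fold, (tr, te) in enumerate(skf.split(X.values, y)):
        clf = ShallowNeuralNetClassifier(
            family=spec.family, max_iter=spec.max_iter, seed=spec.seed
        ).fit(X.values[tr], y[tr])
        y_pred[te] = clf.predict(X.values[te])
        proba = clf.predict_proba(X.values[te])
        for j, c in enumerate(clf.classes_):
            y_score[te, np.flatnonzero(classes == c)[0]] = proba[:, j]
    return _metrics_from_predictions(y, y_pred, y_score, classes)


@dataclass
class TTestReport:
    """Paired accuracy-difference t-test summary.

    ``t`` is formed from the 4-decimal-rounded ``mu`` and ``sigma``;
    ``t_full`` uses full precision.  ``degenerate`` flags a zero sample
    SD (t reported as +inf).
    """

    diffs: np.ndarray
    mu: float
    sigma: float
    t: float
    t_full: float
    df: int
    alpha: float
    interval: tuple[float, float]
    significant: bool
    degenerate: bool = False

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["diffs"] = np.asarray(self.diffs).tolist()
        doc["interval"] = list(self.interval)
        Path(path).write_text(json.dumps(doc, indent=1))


def critical_t(alpha: float, df: int) -> float:
    """Two-tailed Student-t critical value at significance ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def paired_diff_ttest(
    acc_high: np.ndarray, acc_low: np.ndarray, alpha: float = 0.05
) -> TTestReport:
    """Test whether two classifiers' accuracies differ across experiments.

    ``acc_high`` / ``acc_low`` are per-experiment accuracies in percent;
    see the module docstring for the statistic.  The decision compares
    the reported (rounded-chain) ``t`` with the critical interval.
    """

    high = np.asarray(acc_high, dtype=float)
    low = np.asarray(acc_low, dtype=float)
    if high.shape != low.shape:
        raise ValueError("accuracy vectors must have equal lengths")
    n = high.size
    if n < 2:
        raise ValueError(f"need at least 2 paired experiments, got {n}")
    diffs = np.abs(high - low)
    mu = float(diffs.mean())
    sigma = float(diffs.std(ddof=1))
    df = n - 1
    crit = critical_t(alpha, df)
    degenerate = sigma == 0.0
    if degenerate:
        t_rounded = t_full = float("inf") if mu > 0 else 0.0
        logger.warning("zero sample SD of diffs; t reported as %s", t_rounded)
    else:
        mu_r, sigma_r = round(mu, 4), round(sigma, 4)
        t_rounded = float(np.sqrt(n) * mu_r / sigma_r)
        t_full = float(np.sqrt(n) * mu / sigma)
    significant = not (-crit <= t_rounded <= crit)
    return TTestReport(
        diffs=diffs,
        mu=mu,
        sigma=sigma,
        t=t_rounded,
        t_full=t_full,
        df=df,
        alpha=alpha,
        interval=(-crit, crit),
        significant=significant,
        degenerate=degenerate,
    )
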