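"""RFE + KNN classification of window labels with a per-class metric report.

The estimator follows the scikit-learn API: standardize, recursively
eliminate features (multinomial logistic-regression coefficient magnitudes
as the ranking criterion, training data only), then fit a KNN whose K is
chosen by inner cross-validation.  Out-of-fold predictions under stratified
outer CV feed one-vs-rest confusion counts and the accuracy / precision /
recall / F1 metric suite.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)


class RfeKnnClassifier(ClassifierMixin, BaseEstimator):
    """Scaler -> RFE -> inner-CV KNN, as one sklearn estimator.

    Parameters
    ----------
    n_features : int
        Number of features RFE retains (no elimination if >= n input features).
    rfe_step : float
        Fraction of features removed per RFE iteration.
    k_grid : sequence of int
        Candidate neighbor counts for the inner grid search.
    inner_folds : int
        Stratified folds of the inner K selection.
    random_state : int or None
        Seeds the inner CV shuffling; the estimator is otherwise deterministic.
    """

    def __init__(
        self,
        n_features: int = 30,
        rfe_step: float = 0.1,
        k_grid: Sequence[int] = (1, 3, 5, 7, 9),
        inner_folds: int = 3,
        random_state: int | None = None,
    ):
        self.n_features = n_features
        self.rfe_step = rfe_step
        self.k_grid = k_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        check_classification_targets(y)
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        self.classes_ = np.unique(y)
        steps = [("scale", StandardScaler())]
        if self.n_features < X.shape[1]:
            steps.append(
                (
                    "rfe",
                    RFE(
                        LogisticRegression(max_iter=1000),
                        n_features_to_select=self.n_features,
                        step=self.rfe_step,
                    ),
                )
            )
        inner_cv = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=self.random_state
        )
        steps.append(
            (
                "knn",
                GridSearchCV(
                    KNeighborsClassifier(metric="euclidean"),
                    {"n_neighbors": list(self.k_grid)},
                    cv=inner_cv,
                ),
            )
        )
        self.pipeline_ = Pipeline(steps).fit(X, y)
        if "rfe" in self.pipeline_.named_steps:
            self.support_ = self.pipeline_.named_steps["rfe"].support_
        else:
            self.support_ = np.ones(X.shape[1], dtype=bool)
        self.best_k_ = int(self.pipeline_.named_steps["knn"].best_params_["n_neighbors"])
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.pipeline_.predict(X)


def rfe_select(
    X: np.ndarray,
    y: np.ndarray,
    n_keep: int = 30,
    step: float = 0.1,
    feature_names: Sequence[str] | None = None,
) -> list:
    """Recursive feature elimination on (X, y); returns the retained columns.

    Deterministic: the logistic ranking model has no randomness under lbfgs.
    """
    if n_keep < 1:
        raise ConfigurationError("n_keep must be >= 1")
    X = np.asarray(X, dtype=float)
    if n_keep > X.shape[1]:
        raise ConfigurationError(f"n_keep={n_keep} exceeds {X.shape[1]} features")
    names = list(feature_names) if feature_names is not None else list(range(X.shape[1]))
    if n_keep == X.shape[1]:
        return names
    rfe = RFE(
        LogisticRegression(max_iter=1000), n_features_to_select=n_keep, step=step
    ).fit(StandardScaler().fit_transform(X), y)
    return [n for n, keep in zip(names, rfe.support_) if keep]


class CrossvalResult(NamedTuple):
    predictions: np.ndarray
    folds: np.ndarray  # outer-fold index each window was predicted from
    elapsed_s: float


def knn_crossval(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: Sequence[int] = (1, 3, 5, 7, 9),
    n_folds: int = 5,
    seed: int = 42,
    n_features: int = 30,
    rfe_step: float = 0.1,
    inner_folds: int = 3,
) -> CrossvalResult:
    """Out-of-fold predictions under stratified outer CV.

    Within each outer training fold the full model (scaling, RFE, inner-CV K
    selection) is refit from scratch, so no window is ever predicted by a
    model that saw it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        bad = np.unique(y)[np.argmin(counts)]
        raise DataError(
            f"class {bad!r} has {counts.min()} members, fewer than {n_folds} folds"
        )
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    folds = np.empty(y.shape, dtype=int)
    t0 = _time.perf_counter()
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        model = RfeKnnClassifier(
            n_features=min(n_features, X.shape[1]),
            rfe_step=rfe_step,
            k_grid=k_grid,
            inner_folds=inner_folds,
            random_state=seed,
        ).fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
        folds[te] = fold
    return CrossvalResult(pred, folds, _time.perf_counter() - t0)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class Metrics(NamedTuple):
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DataError("predictions do not cover all windows")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1 as fractions in [0, 1].

    Precision/recall with a zero denominator are defined as 0 (logged).
    """
    if c.total == 0:
        raise DataError("all-zero confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        logger.warning("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.warning("no positive instances; recall defined as 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return Metrics(accuracy, precision, recall, f1)


@dataclass
class ClassificationReport:
    """Per-class metric rows (percent, one decimal) plus a mean ± SD summary."""

    per_class: pd.DataFrame  # index: class; columns: accuracy..f1 (percent)
    summary_mean: pd.Series
    summary_sd: pd.Series
    elapsed_s: float | None = None

    def to_table(self) -> pd.DataFrame:
        avg = {
            col: f"{self.summary_mean[col]:.1f} ± {self.summary_sd[col]:.2f}"
            for col in self.per_class.columns
        }
        table = self.per_class.round(1).astype(str)
        table.loc["Average"] = pd.Series(avg)
        return table

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.round(1).to_dict(orient="index"),
            "average": {
                col: {
                    "mean": round(float(self.summary_mean[col]), 1),
                    "sd": round(float(self.summary_sd[col]), 2),
                }
                for col in self.per_class.columns
            },
            "elapsed_s": self.elapsed_s,
        }


def build_report(
    y_true,
    y_pred,
    classes: Sequence | None = None,
    elapsed_s: float | None = None,
) -> ClassificationReport:
    """One-vs-rest metric rows per class with an unweighted mean ± SD summary."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(np.unique(y_true))
    unknown = set(np.unique(y_pred)) - set(classes) | (set(np.unique(y_true)) - set(classes))
    if unknown:
        raise DataError(f"labels {sorted(unknown)} absent from the class list")
    rows = {}
    for cls in classes:
        m = metrics(confusion_counts(y_true, y_pred, cls))
        rows[cls] = {
            "accuracy": 100 * m.accuracy,
            "precision": 100 * m.precision,
            "recall": 100 * m.recall,
            "f1": 100 * m.f1,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return ClassificationReport(
        per_class=per_class,
        summary_mean=per_class.mean(),
        summary_sd=per_class.std(ddof=1),
        elapsed_s=elapsed_s,
    )
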