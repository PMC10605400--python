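"""Univariate Youden-threshold models and multivariate classifier search,
evaluated with repeated stratified k-fold cross-validation.

Univariate models pick the training-set threshold maximizing the Youden
index J = sensitivity + specificity - 1.  Multivariate models standardize
features with training-fold statistics, fit one of six classifier families
(linear discriminant; linear, quadratic and cubic SVM; classification tree;
KNN), derive a Youden-optimal operating threshold from training scores, and
are scored on the held-out fold.  Performance is summarized as mean +- SD of
sensitivity, specificity, PPV, NPV and accuracy over the validation trials,
with undefined ratios (zero denominators) excluded per metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .selection import TrialSplit, partition_stratified

METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")

CLASSIFIER_FAMILIES = ("lda", "svm_linear", "svm_quadratic", "svm_cubic",
                       "tree", "knn")


def make_classifier(family: str) -> BaseEstimator:
    """Fixed-hyperparameter classifier for one of the six families."""
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if family == "svm_quadratic":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0)
    if family == "svm_cubic":
        return SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=1.0)
    if family == "tree":
        return DecisionTreeClassifier(criterion="gini", min_samples_leaf=3,
                                      random_state=0)
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier family {family!r}")


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
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


def metrics_from_confusion(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV, accuracy; NaN where undefined."""
    if counts.total == 0:
        raise ValueError("confusion table is empty")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "ppv": ratio(counts.tp, counts.tp + counts.fp),
        "npv": ratio(counts.tn, counts.tn + counts.fn),
        "accuracy": (counts.tp + counts.tn) / counts.total,
    }


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                           tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()))


# ---------------------------------------------------------------------------
# Youden-threshold univariate model
# ---------------------------------------------------------------------------

@dataclass
class UnivariateModel:
    feature: str
    threshold: float
    orientation: int     # +1: predict positive when value >= threshold
    j: float

    @property
    def informative(self) -> bool:
        return self.j > 0

    def predict(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.threshold) if self.orientation > 0 \
            else (v < self.threshold)


def youden_fit(train_values, train_labels, feature: str = "feature",
               ) -> UnivariateModel:
    """Exhaustive Youden-index threshold scan on the training data.

    Candidate thresholds are the midpoints of consecutive sorted unique
    values plus -inf/+inf sentinels, evaluated for both orientations;
    ties on J are broken toward orientation +1 and then the smallest
    threshold.  Deterministic.
    """
    v = np.asarray(train_values, dtype=float)
    y = np.asarray(train_labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present in training data")
    uniq = np.unique(v)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    pos = np.sort(v[y])
    neg = np.sort(v[~y])
    # orientation +1: sens = P(v >= t | pos), spec = P(v < t | neg)
    sens = 1.0 - np.searchsorted(pos, cands, side="left") / pos.size
    spec = np.searchsorted(neg, cands, side="left") / neg.size
    j_plus = sens + spec - 1.0
    j_minus = -j_plus        # orientation -1 mirrors exactly
    best = None
    for orient, j_arr in ((1, j_plus), (-1, j_minus)):
        k = int(np.argmax(j_arr))          # first (= smallest threshold) max
        if best is None or j_arr[k] > best[0] + 1e-12:
            best = (float(j_arr[k]), orient, float(cands[k]))
    j, orient, thr = best
    return UnivariateModel(feature=feature, threshold=thr, orientation=orient,
                           j=j)


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold classifier with a training-set Youden cut."""

    def __init__(self):
        pass

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("univariate classifier expects one column")
            X = X[:, 0]
        self.model_ = youden_fit(X, y)
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# score-thresholded multivariate model
# ---------------------------------------------------------------------------

class ThresholdedScoreClassifier(ClassifierMixin, BaseEstimator):
    """Standardize -> fit a base classifier -> Youden-threshold its scores.

    The scaler, the base fit, and the operating threshold all use training
    data only.
    """

    def __init__(self, base_estimator=None, standardize=True):
        self.base_estimator = base_estimator
        self.standardize = standardize

    def _score(self, clf, X):
        if hasattr(clf, "decision_function"):
            return np.asarray(clf.decision_function(X), dtype=float)
        return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        self.scaler_ = StandardScaler().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        base = self.base_estimator if self.base_estimator is not None \
            else LinearDiscriminantAnalysis()
        self.estimator_ = clone(base).fit(Xs, y)
        scores = self._score(self.estimator_, Xs)
        self.threshold_model_ = youden_fit(scores, y, feature="score")
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self.threshold_model_.predict(self._score(self.estimator_, Xs))


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    n_repeats: int = 100
    n_folds: int = 5
    seed: int = 0


@dataclass
class ClassifierSpec:
    family: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset must be non-empty")
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class PerformanceSummary:
    """Mean +- SD per metric over validation trials, with per-metric
    contributing-trial counts (undefined ratios are excluded)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_trials: dict[str, int]
    per_trial: pd.DataFrame | None = None

    @classmethod
    def from_trials(cls, rows: list[dict[str, float]],
                    keep_trials: bool = False) -> "PerformanceSummary":
        df = pd.DataFrame(rows, columns=METRICS)
        mean, sd, n = {}, {}, {}
        for metric in METRICS:
            vals = df[metric].dropna()
            n[metric] = int(vals.size)
            mean[metric] = float(vals.mean()) if vals.size else float("nan")
            sd[metric] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return cls(mean=mean, sd=sd, n_trials=n,
                   per_trial=df if keep_trials else None)


def _cv_trials(model_factory, X: np.ndarray, y: np.ndarray,
               splits: list[TrialSplit], keep_trials=False) -> PerformanceSummary:
    rows = []
    for split in splits:
        ytr = y[split.train_idx]
        if ytr.all() or not ytr.any():
            continue
        model = model_factory()
        try:
            model.fit(X[split.train_idx], ytr)
        except (ValueError, np.linalg.LinAlgError):
            continue
        pred = model.predict(X[split.test_idx])
        rows.append(metrics_from_confusion(
            confusion_from_predictions(y[split.test_idx], pred)))
    return PerformanceSummary.from_trials(rows, keep_trials=keep_trials)


def evaluate_univariate(feature_table: pd.DataFrame, labels, feature: str,
                        cv: CVConfig | None = None,
                        splits: list[TrialSplit] | None = None,
                        keep_trials: bool = False) -> PerformanceSummary:
    """Youden-threshold model for one feature under repeated stratified CV."""
    cv = cv or CVConfig()
    if feature not in feature_table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    y = np.asarray(labels).astype(bool)
    if splits is None:
        splits = partition_stratified(y, cv.n_folds, cv.seed,
                                      n_repeats=cv.n_repeats)
    X = feature_table[[feature]].to_numpy(dtype=float)
    return _cv_trials(YoudenThresholdClassifier, X, y, splits,
                      keep_trials=keep_trials)


def multivariate_search(feature_table: pd.DataFrame, labels,
                        selected_pool: list[str],
                        cv: CVConfig | None = None,
                        families: tuple[str, ...] = CLASSIFIER_FAMILIES,
                        max_pool: int = 12,
                        ) -> list[tuple[ClassifierSpec, PerformanceSummary]]:
    """Exhaustive subset x classifier-family search over the selected pool.

    Every non-empty subset of ``selected_pool`` is evaluated with every
    family; results are ranked by mean validation accuracy (ties broken by
    higher mean PPV).
    """
    cv = cv or CVConfig()
    if len(selected_pool) > max_pool:
        raise ValueError(
            f"pool of {len(selected_pool)} features exceeds the exhaustive-"
            f"search limit ({max_pool})")
    y = np.asarray(labels).astype(bool)
    splits = partition_stratified(y, cv.n_folds, cv.seed,
                                  n_repeats=cv.n_repeats)
    results = []
    for r in range(1, len(selected_pool) + 1):
        for subset in itertools.combinations(selected_pool, r):
            X = feature_table[list(subset)].to_numpy(dtype=float)
            for family in families:
                spec = ClassifierSpec(family=family, features=subset)
                summary = _cv_trials(
                    lambda fam=family: ThresholdedScoreClassifier(
                        make_classifier(fam)),
                    X, y, splits)
                results.append((spec, summary))
    results.sort(key=lambda t: (-np.nan_to_num(t[1].mean["accuracy"]),
                                -np.nan_to_num(t[1].mean["ppv"]),
                                t[0].family, t[0].features))
    return results
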