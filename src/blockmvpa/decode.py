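"""Linear-SVM scan decoding with the train-derived [-1, 1] scaling rule.

The classifier chain is sklearn-style: :class:`SymmetricMinMaxScaler`
(per-feature affine map sending the training minimum to -1 and maximum
to +1, applied unchanged to test data, never refit on it) followed by a
soft-margin linear SVM with C = 1.  Accuracy is pooled over all
cross-validation folds: c correct out of n = c + e tested scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FeatureDataset, FoldPlan


@dataclass
class DecoderConfig:
    penalty_C: float = 1.0
    positive_class: str = "Countdown"
    solver_tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty_C <= 0:
            raise ValueError("penalty_C must be positive")


class SymmetricMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-feature affine map: train min -> -1, train max -> +1.

    Test values outside the training range extend linearly beyond
    [-1, 1] (no clipping).  Features constant in training map to 0
    everywhere.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        span = self.data_max_ - self.data_min_
        self.constant_mask_ = span == 0
        span = np.where(self.constant_mask_, 1.0, span)
        self.scale_ = 2.0 / span
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X, ensure_2d=True)
        out = (X - self.data_min_) * self.scale_ - 1.0
        out[:, self.constant_mask_] = 0.0
        return out


class LinearScanClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin linear SVM over scaled scan features.

    Parameters
    ----------
    C : float
        Misclassification penalty (default 1).
    positive_class : str or None
        Label mapped to the positive side of the decision function;
        default ``"Countdown"`` when present, otherwise the first class
        seen.
    tol : float
        Solver tolerance.

    A decision value of exactly 0 predicts the positive class (fixed
    tie rule, needed for determinism).
    """

    def __init__(self, C: float = 1.0, positive_class: str | None = "Countdown", tol: float = 1e-4):
        self.C = C
        self.positive_class = positive_class
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        pos = self.positive_class if self.positive_class in classes else classes[0]
        neg = classes[classes != pos][0]
        self.classes_ = np.array([neg, pos])
        y_num = np.where(y == pos, 1, -1)
        self.scaler_ = SymmetricMinMaxScaler().fit(X)
        self.svc_ = SVC(kernel="linear", C=self.C, tol=self.tol)
        self.svc_.fit(self.scaler_.transform(X), y_num)
        # SVC orients its decision function toward the numerically larger
        # class label; with y in {-1, +1} positive outputs mean ``pos``.
        self.coef_ = self.svc_.coef_.ravel().copy()
        self.intercept_ = float(self.svc_.intercept_[0])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        return self.svc_.decision_function(self.scaler_.transform(X))

    def predict(self, X):
        df = self.decision_function(X)
        neg, pos = self.classes_
        return np.where(df >= 0, pos, neg)


@dataclass
class FoldRecord:
    fold_unit: object
    weights: np.ndarray
    bias: float
    test_index: np.ndarray
    predictions: np.ndarray
    decision_values: np.ndarray
    classifier: LinearScanClassifier | None = None


@dataclass
class ClassifierResult:
    """Pooled cross-validation outcome for one (pair, encoding, scheme)."""

    fold_records: list[FoldRecord]
    classes: np.ndarray  # [negative, positive]
    c: int
    e: int
    confusion: np.ndarray  # rows: true class, cols: predicted

    @property
    def n(self) -> int:
        return self.c + self.e

    @property
    def accuracy(self) -> float:
        return self.c / self.n


def run_cv(
    dataset: FeatureDataset,
    folds: FoldPlan,
    config: DecoderConfig | None = None,
    labels: np.ndarray | None = None,
    keep_classifiers: bool = False,
) -> ClassifierResult:
    """Scale, fit and test a fresh linear SVM per fold; pool the counts.

    ``labels`` overrides the dataset labels (used by the permutation
    test).  Scaling parameters come from training data only.
    """
    config = config or DecoderConfig()
    y_all = dataset.labels if labels is None else np.asarray(labels)
    records = []
    c = e = 0
    classes = None
    y_true_pool, y_pred_pool = [], []
    for unit, (train, test) in zip(folds.fold_units, folds.folds):
        clf = LinearScanClassifier(
            C=config.penalty_C, positive_class=config.positive_class, tol=config.solver_tolerance
        )
        clf.fit(dataset.matrix[train], y_all[train])
        classes = clf.classes_
        dv = clf.decision_function(dataset.matrix[test])
        pred = np.where(dv >= 0, clf.classes_[1], clf.classes_[0])
        correct = pred == y_all[test]
        c += int(correct.sum())
        e += int((~correct).sum())
        y_true_pool.append(y_all[test])
        y_pred_pool.append(pred)
        records.append(
            FoldRecord(
                fold_unit=unit,
                weights=clf.coef_,
                bias=clf.intercept_,
                test_index=test,
                predictions=pred,
                decision_values=dv,
                classifier=clf if keep_classifiers else None,
            )
        )
    conf = confusion_matrix(
        np.concatenate(y_true_pool), np.concatenate(y_pred_pool), labels=list(classes)
    )
    return ClassifierResult(fold_records=records, classes=classes, c=c, e=e, confusion=conf)


def _normalize_unit(values: np.ndarray) -> np.ndarray:
    """Affine map of a 1D series so min -> -1 and max -> +1; constant -> 0."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def decision_timecourse(
    result: ClassifierResult,
    session_matrices: dict[object, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean normalized classifier output over full held-out sessions.

    ``session_matrices`` maps each fold unit to the feature matrix of
    *all* scans of that fold's held-out session(s), rest included (rest
    scans are never used for training or testing; they only appear
    here).  Per fold, raw decision values are affinely mapped to
    [-1, 1] (a constant fold maps to 0), then averaged across folds.
    Returns (mean_timecourse, sd_timecourse).
    """
    if not result.fold_records:
        raise ValueError("no folds in result")
    courses = []
    for rec in result.fold_records:
        if rec.classifier is None:
            raise ValueError("run_cv(..., keep_classifiers=True) is required")
        dv = rec.classifier.decision_function(session_matrices[rec.fold_unit])
        courses.append(_normalize_unit(dv))
    courses = np.vstack(courses)
    return courses.mean(axis=0), courses.std(axis=0)
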