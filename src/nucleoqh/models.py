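"""Classifier construction, cross-validated model choice and evaluation.

Three classifiers (LDA, QDA, random forest) are compared by repeated
stratified 3-fold cross-validation on the training cohort; out-of-fold
scores are pooled per repetition and the model with the highest mean AUC
wins.  The operating point is the score threshold maximizing Youden's J
(sensitivity + specificity - 1) on training scores; held-out evaluation
reports rank-based AUC, the confusion matrix at the operating point and
the derived sensitivity / specificity / PPV / NPV / accuracy.  The
progressor class is positive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .discriminant import RIDGE_EPS, RidgeLDA, RidgeQDA
from .selection import POSITIVE_LABEL

CLASSIFIERS = ("LDA", "QDA", "RF")
N_CV_FOLDS = 3
N_CV_ITER = 100
RF_N_TREES = 100


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: classifier kind + the selected feature names."""

    classifier: str
    features: tuple[str, ...]
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")


@dataclass
class EvalReport:
    """Held-out evaluation: AUC, confusion counts and Table-style metrics.

    Rates are raw fractions; ``percentages`` renders them rounded to the
    nearest integer for reporting.
    """

    auc: float
    operating_point: float
    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tn + self.fp + self.fn + self.tp
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def percentages(self) -> dict[str, int]:
        return {
            "sensitivity": int(round(100 * self.sensitivity)),
            "specificity": int(round(100 * self.specificity)),
            "ppv": int(round(100 * self.ppv)),
            "npv": int(round(100 * self.npv)),
            "accuracy": int(round(100 * self.accuracy)),
        }

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "operating_point": self.operating_point,
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
            "fractions": {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv,
                "npv": self.npv,
                "accuracy": self.accuracy,
            },
            "percent": self.percentages,
        }
        return d


def _base_estimator(kind: str, random_state: int = 0):
    if kind == "LDA":
        return RidgeLDA(ridge=RIDGE_EPS)
    if kind == "QDA":
        return RidgeQDA(ridge=RIDGE_EPS)
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=RF_N_TREES,
            max_features="sqrt",
            max_depth=None,
            random_state=random_state,
        )
    raise ValueError(f"unknown classifier {kind!r}")


class ProgressionClassifier(BaseEstimator, ClassifierMixin):
    """Progression-risk classifier over a fixed feature subset.

    A sklearn-style estimator wrapping LDA, QDA or a random forest; when
    ``features`` is given and the input is a DataFrame, only those columns
    are used.  ``predict_proba``'s positive column is the progressor class.
    """

    def __init__(
        self,
        classifier: str = "RF",
        features: tuple[str, ...] | None = None,
        random_state: int = 0,
    ):
        self.classifier = classifier
        self.features = features
        self.random_state = random_state

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.features is not None:
                missing = [f for f in self.features if f not in X.columns]
                if missing:
                    raise ValueError(f"features missing from input: {missing}")
                return X[list(self.features)].to_numpy(dtype=float)
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.features is not None and X.shape[1] != len(self.features):
            raise ValueError(
                f"expected {len(self.features)} feature columns, got {X.shape[1]}"
            )
        return X

    def fit(self, X, y):
        y = np.asarray(y)
        if y.dtype.kind not in "biu":
            y = y == POSITIVE_LABEL
        y = y.astype(int)
        self.estimator_ = _base_estimator(self.classifier, self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.estimator_.fit(self._matrix(X), y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(self._matrix(X))

    def decision_scores(self, X) -> np.ndarray:
        """Score of the progressor class in [0, 1]."""
        proba = self.predict_proba(X)
        pos_col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, pos_col]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


@dataclass
class CVSummary:
    classifier: str
    auc_mean: float
    auc_sd: float
    acc_mean: float
    acc_sd: float
    sens_mean: float
    sens_sd: float
    spec_mean: float
    spec_sd: float


def cross_validate(
    table: pd.DataFrame,
    spec: ModelSpec,
    folds: int = N_CV_FOLDS,
    iterations: int = N_CV_ITER,
    seed: int = 0,
) -> CVSummary:
    """Repeated stratified k-fold CV of one model on a training cohort.

    Each repetition draws a fresh stratified partition; out-of-fold scores
    are pooled within the repetition for the AUC, and accuracy /
    sensitivity / specificity are computed at score threshold 0.5.  Means
    and SDs are over repetitions.
    """
    y = (table["label"] == POSITIVE_LABEL).to_numpy().astype(int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos % folds or n_neg % folds:
        raise ValueError(
            f"cannot stratify {n_pos}+{n_neg} patients into {folds} equal folds"
        )
    X = table[list(spec.features)].to_numpy(dtype=float)
    aucs, accs, sens, specs = [], [], [], []
    for it in range(iterations):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed * 100003 + it) % (2**31)
        )
        scores = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            clf = ProgressionClassifier(spec.classifier, random_state=spec.random_state)
            clf.fit(X[train_idx], y[train_idx])
            scores[test_idx] = clf.decision_scores(X[test_idx])
        pred = scores >= 0.5
        aucs.append(roc_auc_score(y, scores))
        accs.append(float((pred == y.astype(bool)).mean()))
        sens.append(float(pred[y == 1].mean()))
        specs.append(float((~pred[y == 0]).mean()))
    return CVSummary(
        classifier=spec.classifier,
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)) if iterations > 1 else 0.0,
        acc_mean=float(np.mean(accs)),
        acc_sd=float(np.std(accs, ddof=1)) if iterations > 1 else 0.0,
        sens_mean=float(np.mean(sens)),
        sens_sd=float(np.std(sens, ddof=1)) if iterations > 1 else 0.0,
        spec_mean=float(np.mean(specs)),
        spec_sd=float(np.std(specs, ddof=1)) if iterations > 1 else 0.0,
    )


def select_best_model(
    table: pd.DataFrame,
    features: tuple[str, ...],
    folds: int = N_CV_FOLDS,
    iterations: int = N_CV_ITER,
    seed: int = 0,
) -> tuple[ModelSpec, dict[str, CVSummary]]:
    """Cross-validate LDA, QDA and RF; return the max-mean-AUC spec."""
    summaries = {}
    for kind in CLASSIFIERS:
        spec = ModelSpec(classifier=kind, features=tuple(features), random_state=seed)
        summaries[kind] = cross_validate(table, spec, folds, iterations, seed)
    best = max(CLASSIFIERS, key=lambda k: summaries[k].auc_mean)
    return ModelSpec(classifier=best, features=tuple(features), random_state=seed), summaries


def choose_operating_point(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximizing Youden's J; ties take the lower threshold.

    Candidate thresholds are the midpoints between consecutive distinct
    scores (plus one candidate below the minimum), so the returned point
    is the center of the optimal decision gap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes required to choose an operating point")
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best_thr, best_j = candidates[0], -np.inf
    n_pos, n_neg = labels.sum(), (~labels).sum()
    for thr in candidates:
        pred = scores >= thr
        j = pred[labels].sum() / n_pos + (~pred[~labels]).sum() / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return float(best_thr)


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int, auc: float = float("nan"), operating_point: float = float("nan")) -> EvalReport:
    """Build an :class:`EvalReport` from raw confusion counts."""
    return EvalReport(auc=auc, operating_point=operating_point, tn=tn, fp=fp, fn=fn, tp=tp)


def evaluate(
    model: ProgressionClassifier,
    test: pd.DataFrame,
    threshold: float,
) -> EvalReport:
    """Held-out evaluation of a trained model at a fixed operating point."""
    y = (test["label"] == POSITIVE_LABEL).to_numpy().astype(bool)
    scores = model.decision_scores(test)
    auc = float(roc_auc_score(y, scores))
    pred = scores >= threshold
    return EvalReport(
        auc=auc,
        operating_point=float(threshold),
        tn=int((~pred & ~y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tp=int((pred & y).sum()),
    )


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC of a raw measurement used directly as a score.

    Equals the fraction of (positive, negative) pairs where the positive
    value is larger, counting ties as half.  All-identical values give 0.5
    with a degeneracy warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need at least one patient per class")
    if np.all(values == values[0]):
        warnings.warn("constant measurement: AUC is 0.5 by convention")
        return 0.5
    return float(roc_auc_score(labels, values))
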