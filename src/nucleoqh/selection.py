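"""Repeated-split feature identification.

The training cohort is repeatedly split in half with class stratification.
On each half-A, two six-feature sets are chosen — one by Wilcoxon rank-sum
p-values, one by Welch t-test p-values — and each set is used to train an
LDA and a QDA classifier on half-A; every selector x classifier record is
scored by its AUC on half-B.  After ``n_iter`` iterations (default 30,
giving 120 records), records with validation AUC >= 0.65 are retained and
the six features recurring most often among retained records are the
final discriminative set.  Ties are broken deterministically: total
occurrences across all records, then mean selection rank, then manifest
order.

``RepeatedSplitFeatureSelector`` exposes the procedure as a sklearn-style
estimator (fit on a feature matrix + labels; ``selected_features_`` holds
the final six names).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .discriminant import RIDGE_EPS, RidgeLDA, RidgeQDA

from .manifest import canonical_manifest

POSITIVE_LABEL = "progressor"
NEGATIVE_LABEL = "non-progressor"
N_SELECT = 6
N_ITER = 30
RETENTION_AUC = 0.65
_RIDGE = RIDGE_EPS  # covariance regularization for the discriminant models


@dataclass
class SelectionRecord:
    iteration: int
    selector: str  # WLCX | TT
    classifier: str  # LDA | QDA
    features: list[str]
    ranks: list[int]  # selection rank of each feature (0 = best p-value)
    auc: float


@dataclass
class SelectionResult:
    records: list[SelectionRecord]
    retained: list[SelectionRecord]
    tally: dict[str, int]  # recurrence among retained records
    selected: list[str]  # final six feature names


def _validate_cohort(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = [c for c in table.columns if c not in ("patient_id", "label")]
    X = table[names].to_numpy(dtype=float)
    y = (table["label"] == POSITIVE_LABEL).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return X, y, names


def _feature_pvalues(X: np.ndarray, y: np.ndarray, selector: str) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-value and |standardized effect| per feature column."""
    pos, neg = X[y], X[~y]
    const = X.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if selector == "WLCX":
            res = stats.mannwhitneyu(pos, neg, alternative="two-sided", axis=0)
            pvals = np.asarray(res.pvalue, dtype=float)
        elif selector == "TT":
            res = stats.ttest_ind(pos, neg, equal_var=False, axis=0)
            pvals = np.asarray(res.pvalue, dtype=float)
        else:
            raise ValueError(f"unknown selector {selector!r}")
    pooled = np.sqrt(0.5 * (pos.var(ddof=1, axis=0) + neg.var(ddof=1, axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = np.abs(pos.mean(axis=0) - neg.mean(axis=0)) / pooled
    effect[~np.isfinite(effect)] = 0.0
    pvals[~np.isfinite(pvals)] = 1.0
    pvals[const] = 1.0  # constant features are never selected
    effect[const] = 0.0
    return pvals, effect


def rank_features(
    table: pd.DataFrame, selector: str = "WLCX", k: int = N_SELECT
) -> list[str]:
    """Top-k feature names by ascending two-sided p-value.

    Ties are broken by descending absolute standardized effect size, then
    by manifest order (column order of the table).
    """
    X, y, names = _validate_cohort(table)
    pvals, effect = _feature_pvalues(X, y, selector)
    order = np.lexsort((np.arange(len(names)), -effect, pvals))
    return [names[i] for i in order[:k]]


def _make_classifier(kind: str):
    if kind == "LDA":
        return RidgeLDA(ridge=_RIDGE)
    if kind == "QDA":
        return RidgeQDA(ridge=_RIDGE)
    raise ValueError(f"unknown classifier {kind!r}")


def _stratified_half_split(y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    a_idx, b_idx = [], []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        half = len(idx) // 2
        a_idx.append(perm[:half])
        b_idx.append(perm[half:])
    return np.sort(np.concatenate(a_idx)), np.sort(np.concatenate(b_idx))


def identify_features(
    table: pd.DataFrame,
    n_iter: int = N_ITER,
    retention_auc: float = RETENTION_AUC,
    seed: int = 0,
    k: int = N_SELECT,
    retention_scope: str = "record",
) -> SelectionResult:
    """Run the repeated-split identification procedure on a training cohort.

    ``retention_scope`` is "record" (retain each selector x classifier
    record on its own AUC) or "iteration" (retain an iteration's four
    records only if all four pass).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X, y, names = _validate_cohort(table)
    if (y.sum() != (~y).sum()):
        raise ValueError("training cohort must be class-balanced")
    if retention_scope not in ("record", "iteration"):
        raise ValueError("retention_scope must be 'record' or 'iteration'")
    rng = np.random.default_rng(seed)
    name_idx = {n: i for i, n in enumerate(names)}
    records: list[SelectionRecord] = []
    for it in range(n_iter):
        a_idx, b_idx = _stratified_half_split(y, rng)
        Xa, ya = X[a_idx], y[a_idx]
        Xb, yb = X[b_idx], y[b_idx]
        for selector in ("WLCX", "TT"):
            pvals, effect = _feature_pvalues(Xa, ya, selector)
            order = np.lexsort((np.arange(len(names)), -effect, pvals))
            feats = [names[i] for i in order[:k]]
            cols = [name_idx[f] for f in feats]
            for clf_name in ("LDA", "QDA"):
                clf = _make_classifier(clf_name)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(Xa[:, cols], ya)
                    scores = clf.predict_proba(Xb[:, cols])[:, 1]
                records.append(
                    SelectionRecord(
                        iteration=it,
                        selector=selector,
                        classifier=clf_name,
                        features=feats,
                        ranks=list(range(k)),
                        auc=float(roc_auc_score(yb, scores)),
                    )
                )
    if retention_scope == "record":
        retained = [r for r in records if r.auc >= retention_auc]
    else:
        by_iter: dict[int, list[SelectionRecord]] = {}
        for r in records:
            by_iter.setdefault(r.iteration, []).append(r)
        retained = [
            r
            for recs in by_iter.values()
            if all(x.auc >= retention_auc for x in recs)
            for r in recs
        ]
    if not retained:
        raise ValueError("no combinations retained at the requested AUC threshold")
    tally: dict[str, int] = {}
    total: dict[str, int] = {}
    rank_sum: dict[str, list[int]] = {}
    for r in records:
        for f, rk in zip(r.features, r.ranks):
            total[f] = total.get(f, 0) + 1
            rank_sum.setdefault(f, []).append(rk)
    for r in retained:
        for f in r.features:
            tally[f] = tally.get(f, 0) + 1
    manifest_order = {n: i for i, n in enumerate(names)}

    def sort_key(f: str):
        return (
            -tally.get(f, 0),
            -total.get(f, 0),
            float(np.mean(rank_sum[f])),
            manifest_order[f],
        )

    candidates = sorted(tally.keys(), key=sort_key)
    selected = candidates[:k]
    if len(selected) < k:  # pathological: fewer distinct features than k
        extras = sorted((f for f in total if f not in tally), key=sort_key)
        selected = (selected + extras)[:k]
    return SelectionResult(records=records, retained=retained, tally=tally, selected=selected)


class RepeatedSplitFeatureSelector(BaseEstimator):
    """Sklearn-style wrapper around :func:`identify_features`.

    Fitted attributes: ``selected_features_`` (six names),
    ``selection_result_`` (full record set), ``support_`` (boolean mask in
    column order).  ``transform`` subsets a matrix or DataFrame to the
    selected columns.
    """

    def __init__(
        self,
        n_iter: int = N_ITER,
        retention_auc: float = RETENTION_AUC,
        k: int = N_SELECT,
        retention_scope: str = "record",
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.retention_auc = retention_auc
        self.k = k
        self.retention_scope = retention_scope
        self.random_state = random_state

    def fit(self, X, y=None):
        table = self._as_table(X, y)
        self.feature_names_in_ = np.array(
            [c for c in table.columns if c not in ("patient_id", "label")], dtype=object
        )
        self.selection_result_ = identify_features(
            table,
            n_iter=self.n_iter,
            retention_auc=self.retention_auc,
            seed=self.random_state,
            k=self.k,
            retention_scope=self.retention_scope,
        )
        self.selected_features_ = list(self.selection_result_.selected)
        self.support_ = np.isin(self.feature_names_in_, self.selected_features_)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)[:, self.support_]

    @staticmethod
    def _as_table(X, y) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if "label" in X.columns:
                return X
            table = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            names = canonical_manifest().names
            if X.shape[1] != len(names):
                names = [f"f{i}" for i in range(X.shape[1])]
            table = pd.DataFrame(X, columns=names)
        if y is None:
            raise ValueError("labels required (pass y or a 'label' column)")
        y = np.asarray(y)
        if y.dtype.kind in "biu":
            table["label"] = np.where(y.astype(bool), POSITIVE_LABEL, NEGATIVE_LABEL)
        else:
            table["label"] = y
        return table


def clustergram(
    table: pd.DataFrame, features: list[str]
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Hierarchical co-clustering of patients and selected features.

    Distance is 1 - Spearman correlation (between patients over the
    selected features, and between features over patients); linkage is
    average.  Returns (patient linkage, feature linkage, per-feature
    z-scored matrix for heatmap display).  Constant features are dropped
    with a warning (their correlations are undefined).
    """
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    mat = table[list(features)].to_numpy(dtype=float)
    keep = mat.std(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        warnings.warn(f"dropping constant features from clustergram: {dropped}")
        features = [f for f, k in zip(features, keep) if k]
        mat = mat[:, keep]
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 non-constant features to cluster")

    def _spearman_condensed(rows: np.ndarray) -> np.ndarray:
        rho = stats.spearmanr(rows.T).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        d = 1.0 - rho
        np.fill_diagonal(d, 0.0)
        iu = np.triu_indices(len(rows), k=1)
        return d[iu]

    row_link = linkage(_spearman_condensed(mat), method="average")
    col_link = linkage(_spearman_condensed(mat.T), method="average")
    z = (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=0)
    zdf = pd.DataFrame(z, columns=features, index=table.get("patient_id", None))
    return row_link, col_link, zdf
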