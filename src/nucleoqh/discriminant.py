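"""Ridge-regularized Gaussian discriminant classifiers.

Linear and quadratic discriminant analysis with an additive ridge on the
covariance diagonal (eps * mean-variance * I), so class covariances stay
positive definite even on tiny training halves (15 patients x 6 features)
with collinear or near-constant features.  API follows sklearn
conventions (fit / predict_proba / predict, ``classes_``).
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin

RIDGE_EPS = 1e-4


class _RidgeDiscriminant(BaseEstimator, ClassifierMixin):
    pooled: bool  # True -> LDA (shared covariance), False -> QDA

    def __init__(self, ridge: float = RIDGE_EPS):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        n, p = X.shape
        self.means_ = np.stack([X[y_idx == k].mean(axis=0) for k in range(2)])
        self.priors_ = np.bincount(y_idx, minlength=2) / n
        scale = max(float(X.var(axis=0).mean()), 1e-12)
        eye = self.ridge * scale * np.eye(p)
        if self.pooled:
            resid = X - self.means_[y_idx]
            cov = (resid.T @ resid) / max(n - 2, 1) + eye
            covs = [cov, cov]
        else:
            covs = []
            for k in range(2):
                xk = X[y_idx == k]
                resid = xk - self.means_[k]
                covs.append((resid.T @ resid) / max(len(xk) - 1, 1) + eye)
        self._chol = [np.linalg.cholesky(c) for c in covs]
        self._logdet = [2.0 * np.log(np.diag(c)).sum() for c in self._chol]
        return self

    def _log_likelihood(self, X) -> np.ndarray:
        from scipy.linalg import solve_triangular

        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), 2))
        for k in range(2):
            diff = (X - self.means_[k]).T
            z = solve_triangular(self._chol[k], diff, lower=True)
            maha = (z**2).sum(axis=0)
            out[:, k] = -0.5 * (maha + self._logdet[k]) + np.log(self.priors_[k])
        return out

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self._log_likelihood(X), axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


class RidgeLDA(_RidgeDiscriminant):
    """Linear discriminant: pooled covariance + additive ridge."""

    pooled = True


class RidgeQDA(_RidgeDiscriminant):
    """Quadratic discriminant: per-class covariance + additive ridge."""

    pooled = False
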