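"""Motor-imagery decoding: common spatial patterns + linear discriminant.

Both estimators follow the scikit-learn protocol (``fit`` / ``transform`` /
``predict``, ``get_params``, trailing-underscore fitted attributes) so they
compose with sklearn pipelines and model selection, but the math is
implemented here from the generalized-eigendecomposition and
pooled-covariance formulas.

CSP jointly diagonalizes the two class covariances: the filters are the
eigenvectors of ``eig(C_a, C_a + C_b)`` and the top/bottom ``n_filters``
pairs maximize the between-class variance ratio.  Features are
log-normalized variances of the spatially filtered trials.  The linear
discriminant scores trials with ``w = S_pooled^-1 (mu_1 - mu_0)``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin


def _trial_covariances(X: np.ndarray) -> np.ndarray:
    """Per-trial spatial covariances, trace-normalized."""
    covs = np.einsum("tcs,tds->tcd", X, X) / X.shape[2]
    traces = np.trace(covs, axis1=1, axis2=2)
    return covs / traces[:, None, None]


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    n = cov.shape[0]
    return (1.0 - gamma) * cov + gamma * (np.trace(cov) / n) * np.eye(n)


class CSP(BaseEstimator, TransformerMixin):
    """Common spatial patterns for two-class EEG trials.

    Parameters
    ----------
    n_filters : int
        Number of filter *pairs*; ``2 * n_filters`` filters are kept (those
        maximizing variance for each class).
    shrinkage : float
        Covariance shrinkage toward scaled identity in [0, 1]; guards
        against rank deficiency on short trials.  With ``shrinkage=0`` a
        singular pooled covariance raises.

    Attributes
    ----------
    filters_ : ndarray, (2 * n_filters, n_channels)
        Spatial filters, rows ordered from most class-0-dominant to most
        class-1-dominant.
    eigenvalues_ : ndarray
        Generalized eigenvalues (class-0 variance fraction) of the kept
        filters, in the same order.
    classes_ : ndarray
    """

    def __init__(self, n_filters: int = 3, shrinkage: float = 0.05):
        self.n_filters = n_filters
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CSP":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_channels, n_samples)")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("CSP requires exactly two classes")
        covs = []
        for cls in self.classes_:
            trials = X[y == cls]
            if trials.shape[0] < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 trials")
            covs.append(_shrink(_trial_covariances(trials).mean(axis=0),
                                self.shrinkage))
        c_a, c_b = covs
        pooled = c_a + c_b
        if np.linalg.matrix_rank(pooled) < pooled.shape[0]:
            raise np.linalg.LinAlgError(
                "pooled covariance is rank deficient; raise `shrinkage` "
                "(e.g. 0.05) or supply longer trials"
            )
        # eigenvalues ascending in [0, 1]: fraction of variance from class a
        eigvals, eigvecs = linalg.eigh(c_a, pooled)
        order = np.argsort(eigvals)
        pick = np.concatenate([order[: self.n_filters],
                               order[-self.n_filters:]])
        self.filters_ = eigvecs[:, pick].T
        self.eigenvalues_ = eigvals[pick]
        if np.all(np.abs(self.eigenvalues_ - 0.5) < 0.05):
            warnings.warn("class covariances are nearly identical; CSP "
                          "filters carry no discriminative information",
                          stacklevel=2)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Log-normalized variance features, (n_trials, 2 * n_filters)."""
        X = np.asarray(X, dtype=np.float64)
        filtered = np.einsum("fc,tcs->tfs", self.filters_, X)
        var = filtered.var(axis=2)
        return np.log(var / var.sum(axis=1, keepdims=True))


class LinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Two-class Fisher linear discriminant on feature vectors.

    ``coef_`` is proportional to ``S_pooled^-1 (mu_1 - mu_0)`` with the
    pooled covariance weighted by per-class ``n - 1``.  A singular pooled
    covariance is ridge-regularized with the logged ``ridge_`` coefficient
    rather than raising.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearDiscriminant":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LinearDiscriminant requires exactly two classes")
        mus, covs, ns = [], [], []
        for cls in self.classes_:
            grp = X[y == cls]
            mus.append(grp.mean(axis=0))
            covs.append(np.cov(grp, rowvar=False, ddof=1))
            ns.append(grp.shape[0])
        pooled = ((ns[0] - 1) * np.atleast_2d(covs[0])
                  + (ns[1] - 1) * np.atleast_2d(covs[1])) / (sum(ns) - 2)
        self.ridge_ = 0.0
        try:
            w = linalg.solve(pooled, mus[1] - mus[0], assume_a="pos")
        except (linalg.LinAlgError, ValueError):
            self.ridge_ = self.ridge if self.ridge > 0 else 1e-8
            w = linalg.solve(pooled + self.ridge_ * np.eye(pooled.shape[0]),
                             mus[1] - mus[0])
        self.coef_ = w
        self.intercept_ = -float(w @ (mus[0] + mus[1]) / 2.0)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


def fit_csp(trials_a: np.ndarray, trials_b: np.ndarray,
            n_filters: int = 3, shrinkage: float = 0.05) -> CSP:
    """Fit CSP from two stacks of (n_trials, n_channels, n_samples)."""
    X = np.concatenate([trials_a, trials_b], axis=0)
    y = np.array([0] * len(trials_a) + [1] * len(trials_b))
    return CSP(n_filters=n_filters, shrinkage=shrinkage).fit(X, y)


def fit_lda(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminant:
    """Fit the linear discriminant on CSP log-variance features."""
    return LinearDiscriminant().fit(features, labels)


def generate_mi_trials(
    n_trials: int,
    n_channels: int = 8,
    n_samples: int = 250,
    erd_channel: int = 0,
    separation: float = 4.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic two-class trials for decoder exercises.

    Rest trials are unit-variance Gaussian noise on all channels; motor
    imagery trials carry ``1 + separation`` variance on ``erd_channel``
    (an event-related power change on one sensorimotor channel).
    ``separation=0`` produces indistinguishable classes (chance decoding).
    Returns (X, y) with y in {"rest", "MI"}, alternating cues.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_trials, n_channels, n_samples))
    y = np.array(["rest", "MI"] * ((n_trials + 1) // 2))[:n_trials]
    scale = np.sqrt(1.0 + separation)
    for t in np.flatnonzero(y == "MI"):
        X[t, erd_channel] *= scale
    return X, y
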