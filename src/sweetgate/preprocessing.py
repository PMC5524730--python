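"""Column scalers used by the descriptor-based classifiers.

Autoscaling (column-wise standardization) is the convention for PLS-family
models; range scaling to [0,1] is the convention for similarity-based
classification with the average Euclidean metric, because it bounds every
per-column squared difference — and hence the average Euclidean distance —
inside [0,1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class ConstantColumnError(ValueError):
    pass


def _check_non_constant(X: np.ndarray, spread: np.ndarray) -> None:
    bad = np.where(spread <= 0)[0]
    if bad.size:
        raise ConstantColumnError(f"constant column(s) at index {bad.tolist()}")


class Autoscaler(BaseEstimator, TransformerMixin):
    """Center to mean 0 and scale to unit standard deviation per column.

    Parameters
    ----------
    ddof : int, default 1
        Degrees of freedom for the standard deviation; the default is the
        sample (n-1) convention.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        _check_non_constant(X, self.scale_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted matrix")
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


class RangeScaler(BaseEstimator, TransformerMixin):
    """Scale each column to [0,1] by its training min/max; test values are clipped."""

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        _check_non_constant(X, self.max_ - self.min_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted matrix")
        return np.clip((X - self.min_) / (self.max_ - self.min_), 0.0, 1.0)


def fit_scaler(X, method: str = "autoscale"):
    """Fit a scaler of the named method ('autoscale' or 'range')."""
    if method == "autoscale":
        return Autoscaler().fit(X)
    if method == "range":
        return RangeScaler().fit(X)
    raise ValueError(f"unknown scaling method {method!r}")


def apply_scaler(scaler, X):
    return scaler.transform(X)
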