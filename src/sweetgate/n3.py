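"""N3 (N-nearest neighbors) similarity classifier.

Every training molecule contributes to the class score of a query, weighted
by its similarity to the query divided by its similarity rank raised to an
exponent alpha.  Similarity is 1 - d where d is the average Euclidean
distance on range-scaled descriptors,

    d_i = sqrt( (1/p) * sum_j (x_j - x_ij)^2 )  in [0, 1],

so s_i = 1 - d_i is also bounded in [0, 1].  Ranks are assigned by
decreasing similarity (rank 1 = most similar); tied similarities receive the
average rank of the tied block so that the classifier is independent of
training-row order.  Class scores are normalized to sum to one; the class
with the larger score is assigned, an exact tie is a rejection.

Small alpha spreads influence over many neighbors; large alpha concentrates
it on the nearest one (alpha -> infinity recovers 1-NN).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datasets import NOT_ASSIGNED
from .preprocessing import RangeScaler


class N3Classifier(BaseEstimator, ClassifierMixin):
    """Rank-weighted similarity classifier with rejection on ties.

    Parameters
    ----------
    alpha : float, default 1.5
        Rank-weight exponent; must be positive.
    """

    def __init__(self, alpha: float = 1.5):
        self.alpha = alpha

    def fit(self, X, y):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        self.scaler_ = RangeScaler().fit(X)
        self.X_train_ = self.scaler_.transform(X)
        self.y_train_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _similarities(self, Xs: np.ndarray) -> np.ndarray:
        # average Euclidean distance on range-scaled data, bounded in [0,1]
        diff = Xs[:, None, :] - self.X_train_[None, :, :]
        d = np.sqrt(np.mean(diff ** 2, axis=2))
        return 1.0 - d

    def average_similarity(self, X) -> np.ndarray:
        """Mean similarity of each query to the whole training set (AD support)."""
        check_is_fitted(self, "X_train_")
        Xs = self.scaler_.transform(check_array(X, dtype=float))
        return self._similarities(Xs).mean(axis=1)

    def training_self_similarity(self) -> np.ndarray:
        """Each training molecule's mean similarity to the other training molecules."""
        check_is_fitted(self, "X_train_")
        S = self._similarities(self.X_train_)
        n = S.shape[0]
        return (S.sum(axis=1) - 1.0) / (n - 1)

    def predict_proba(self, X) -> np.ndarray:
        """Per-class scores; each row is a probability vector (sums to 1)."""
        check_is_fitted(self, "X_train_")
        Xs = self.scaler_.transform(check_array(X, dtype=float))
        S = self._similarities(Xs)
        # rank 1 = most similar; ties get the average rank of the tied block
        ranks = rankdata(-S, axis=1, method="average")
        contrib = S / ranks ** self.alpha
        totals = contrib.sum(axis=1, keepdims=True)
        zero = totals[:, 0] <= 0
        if zero.any():
            warnings.warn("query with zero total similarity; uniform class scores")
        proba = np.empty((Xs.shape[0], self.classes_.size))
        for k, c in enumerate(self.classes_):
            proba[:, k] = contrib[:, self.y_train_ == c].sum(axis=1)
        proba[~zero] /= totals[~zero]
        proba[zero] = 1.0 / self.classes_.size
        return proba

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        out = np.empty(proba.shape[0], dtype=object)
        for i, row in enumerate(proba):
            top = row.max()
            if np.count_nonzero(row == top) > 1:
                out[i] = NOT_ASSIGNED
            else:
                out[i] = self.classes_[int(np.argmax(row))]
        return out


def fit_n3(X, y, alpha: float = 1.5) -> N3Classifier:
    return N3Classifier(alpha=alpha).fit(X, y)


def n3_class_scores(model: N3Classifier, x) -> np.ndarray:
    """Class scores for a single query row."""
    return model.predict_proba(np.atleast_2d(x))[0]


def predict_n3(model: N3Classifier, X) -> np.ndarray:
    return model.predict(X)
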