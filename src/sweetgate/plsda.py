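"""Partial least squares discriminant analysis (PLS2 + class assignment).

PLSDA regresses a two-column class dummy matrix ({1,0} for the first class,
{0,1} for the second) on autoscaled descriptors with the NIPALS PLS2
algorithm, extracting latent variables (LVs) — orthogonal linear
combinations of the descriptors — and assigns each sample to the class with
the larger predicted response.  An exact tie is a rejection (not-assigned).

The score matrix is kept for leverage-based applicability-domain checks:
h = t'(T'T)⁻¹t, with the usual cutoff h* = 3·(number of LVs)/n_train.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datasets import NOT_ASSIGNED
from .preprocessing import Autoscaler

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis with rejection on tied responses.

    Parameters
    ----------
    n_lv : int, default 1
        Number of latent variables.
    ddof : int, default 1
        Standard-deviation convention for autoscaling.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels, sorted.
    x_weights_, x_loadings_ : ndarray (p, n_lv)
    y_loadings_ : ndarray (2, n_lv)
    x_scores_ : ndarray (n, n_lv)
        Training LV scores; mutually orthogonal.
    coef_ : ndarray (p, 2)
        Regression coefficients on the autoscaled X / centered dummy Y scale.
    """

    def __init__(self, n_lv: int = 1, ddof: int = 1):
        self.n_lv = n_lv
        self.ddof = ddof

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("PLSDA here is a two-class discriminant; got "
                             f"{classes.size} class(es)")
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        if X.shape[0] < self.n_lv + 2:
            raise ValueError("need at least n_lv + 2 samples")
        self.classes_ = classes
        self.scaler_ = Autoscaler(ddof=self.ddof).fit(X)
        Xs = self.scaler_.transform(X)
        rank = np.linalg.matrix_rank(Xs)
        if self.n_lv > rank:
            raise ValueError(f"n_lv={self.n_lv} exceeds rank {rank} of the scaled matrix")

        Y = np.column_stack([(y == c).astype(float) for c in classes])
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_

        n, p = Xs.shape
        W = np.zeros((p, self.n_lv))
        P = np.zeros((p, self.n_lv))
        Q = np.zeros((2, self.n_lv))
        T = np.zeros((n, self.n_lv))
        Xr, Yr = Xs.copy(), Yc.copy()
        for a in range(self.n_lv):
            u = Yr[:, np.argmax(np.sum(Yr ** 2, axis=0))].copy()
            w = np.zeros(p)
            for _ in range(_NIPALS_MAX_ITER):
                w_new = Xr.T @ u
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    raise ValueError("degenerate residual; reduce n_lv")
                w_new /= norm
                t = Xr @ w_new
                q = Yr.T @ t / (t @ t)
                u_new = Yr @ q / (q @ q)
                if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                    w, u = w_new, u_new
                    break
                w, u = w_new, u_new
            t = Xr @ w
            p_load = Xr.T @ t / (t @ t)
            q = Yr.T @ t / (t @ t)
            Xr = Xr - np.outer(t, p_load)
            Yr = Yr - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t

        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, Q, T
        # R maps scaled X directly to scores: T = Xs @ R
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.coef_ = self.x_rotations_ @ Q.T
        self.n_features_in_ = p
        self.n_train_ = n
        self._score_gram_inv_ = np.linalg.inv(T.T @ T)
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Predicted dummy responses, one column per class in ``classes_`` order."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        Xs = self.scaler_.transform(X)
        return Xs @ self.coef_ + self.y_mean_

    def transform(self, X) -> np.ndarray:
        """Project onto the latent-variable score space."""
        check_is_fitted(self, "x_rotations_")
        X = check_array(X, dtype=float)
        return self.scaler_.transform(X) @ self.x_rotations_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        out = np.empty(scores.shape[0], dtype=object)
        for i, row in enumerate(scores):
            if row[0] == row[1]:
                out[i] = NOT_ASSIGNED
            else:
                out[i] = self.classes_[int(np.argmax(row))]
        return out

    def leverage(self, X) -> np.ndarray:
        """h = t'(T'T)⁻¹t of each sample in the training score space."""
        T = self.transform(X)
        return np.einsum("ij,jk,ik->i", T, self._score_gram_inv_, T)

    @property
    def leverage_threshold_(self) -> float:
        check_is_fitted(self, "x_scores_")
        return 3.0 * self.n_lv / self.n_train_


def fit_plsda(X, y, n_lv: int = 1) -> PLSDAClassifier:
    return PLSDAClassifier(n_lv=n_lv).fit(X, y)


def predict_plsda(model: PLSDAClassifier, X) -> np.ndarray:
    return model.predict(X)
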