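"""Venetian-blinds cross-validation and grid hyperparameter optimization.

Venetian-blinds CV assigns sample i (0-based, in stored order) to
cancelation group i mod G, so every sample is held out exactly once and the
folds interleave through the data like blind slats.  Hyperparameters (the
N3 alpha exponent, the PLSDA latent-variable count) are chosen by the lowest
classification error rate (1 - NER) in this cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import clone

from .metrics import class_metrics


class FoldError(ValueError):
    pass


def venetian_blind_cv(X, y, estimator, n_groups: int = 5) -> np.ndarray:
    """Out-of-fold predictions under the i-mod-G fold scheme.

    Every training fold must contain both classes; otherwise the error
    suggests reordering the samples in a stratified (class-interleaved) way.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = y.size
    if n < n_groups:
        raise FoldError(f"need at least {n_groups} samples for {n_groups} groups")
    fold_of = np.arange(n) % n_groups
    classes = np.unique(y)
    predictions = np.empty(n, dtype=object)
    for g in range(n_groups):
        held_out = fold_of == g
        y_train = y[~held_out]
        if np.unique(y_train).size < classes.size:
            raise FoldError(
                f"training fold {g} lost a class; reorder samples stratified by class"
            )
        model = clone(estimator).fit(X[~held_out], y_train)
        predictions[held_out] = model.predict(X[held_out])
    return predictions


def cv_error(X, y, estimator, n_groups: int = 5) -> float:
    """Cross-validated classification error rate 1 - NER."""
    y_pred = venetian_blind_cv(X, y, estimator, n_groups)
    return 1.0 - class_metrics(y, y_pred, context="cv").ner


@dataclass
class GridSearchResult:
    best_value: float | int
    best_error: float
    grid: list
    errors: list[float]


DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
DEFAULT_LV_GRID: tuple[int, ...] = tuple(range(1, 11))


def optimize_hyperparameter(
    X,
    y,
    estimator,
    param_name: str,
    grid: Sequence,
    n_groups: int = 5,
    prefer: str = "smaller",
) -> GridSearchResult:
    """Pick the grid value minimizing the CV error rate.

    Ties break toward the simpler model: ``prefer='smaller'`` (fewer latent
    variables) or ``prefer='larger'`` (a larger alpha, concentrating on
    fewer effective neighbors).  Grid points whose model cannot be fitted
    (e.g. more latent variables than the training rank) are recorded with an
    error of infinity.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if prefer not in ("smaller", "larger"):
        raise ValueError("prefer must be 'smaller' or 'larger'")
    errors: list[float] = []
    for value in grid:
        model = clone(estimator).set_params(**{param_name: value})
        try:
            errors.append(cv_error(X, y, model, n_groups))
        except (ValueError, FoldError):
            errors.append(float("inf"))
    errors_arr = np.asarray(errors)
    best_error = errors_arr.min()
    tied = [v for v, e in zip(grid, errors) if e == best_error]
    best_value = min(tied) if prefer == "smaller" else max(tied)
    return GridSearchResult(best_value=best_value, best_error=float(best_error),
                            grid=list(grid), errors=errors)
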