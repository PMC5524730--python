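"""Rejection-aware classification metrics, stratified splitting, Monte Carlo validation.

A consensus classifier may refuse to assign a molecule; such rejections are
excluded from both the numerator and the denominator of sensitivity and
specificity, and reported separately as the not-assigned percentage.  The
non-error rate (NER) is the mean of the two per-class sensitivities, which
is robust to class imbalance; in the two-class setting the sensitivity of
one class equals the specificity of the other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import NOT_ASSIGNED, SWEET, NON_SWEET


class MetricsError(ValueError):
    pass


@dataclass
class ValidationReport:
    """NER / Sn / Sp over assigned molecules plus the not-assigned percentage."""

    ner: float
    sn_sweet: float
    sp_sweet: float
    pct_not_assigned: float
    confusion: dict[str, int] = field(default_factory=dict)
    context: str = "fitting"

    def __post_init__(self) -> None:
        if not np.isclose(self.ner, (self.sn_sweet + self.sp_sweet) / 2.0, atol=1e-12):
            raise MetricsError("NER must equal (Sn + Sp)/2")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def as_row(self) -> dict:
        return {
            "context": self.context,
            "NER": self.ner,
            "Sn": self.sn_sweet,
            "Sp": self.sp_sweet,
            "% not assigned": self.pct_not_assigned,
        }


def reports_to_table(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    """Summary table, one row per validation context."""
    return pd.DataFrame([r.as_row() for r in reports]).set_index("context")


def class_metrics(
    y_true,
    y_pred,
    positive: str = SWEET,
    negative: str = NON_SWEET,
    context: str = "fitting",
) -> ValidationReport:
    """Sensitivity/specificity of the positive class over assigned molecules.

    ``y_pred`` may contain the rejection label ``not-assigned``; rejected
    molecules contribute only to ``pct_not_assigned``.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise MetricsError("y_true and y_pred must have equal length")
    n = y_true.size
    assigned = y_pred != NOT_ASSIGNED
    pct_na = 100.0 * np.count_nonzero(~assigned) / n if n else 0.0
    yt, yp = y_true[assigned], y_pred[assigned]
    n_pos = np.count_nonzero(yt == positive)
    n_neg = np.count_nonzero(yt == negative)
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("a class has zero assigned molecules; metrics undefined")
    tp = int(np.count_nonzero((yt == positive) & (yp == positive)))
    tn = int(np.count_nonzero((yt == negative) & (yp == negative)))
    sn = tp / n_pos
    sp = tn / n_neg
    confusion = {
        "tp": tp,
        "fn": n_pos - tp,
        "tn": tn,
        "fp": n_neg - tn,
        "not_assigned": int(np.count_nonzero(~assigned)),
        "total": int(n),
    }
    return ValidationReport(
        ner=(sn + sp) / 2.0,
        sn_sweet=sn,
        sp_sweet=sp,
        pct_not_assigned=pct_na,
        confusion=confusion,
        context=context,
    )


def stratified_split(labels, n_test: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random class-proportional train/test split with largest-remainder rounding.

    Per-class test counts are ``n_test * class_size / n`` rounded down, with
    the remaining seats given to the classes with the largest fractional
    remainders so the counts sum exactly to ``n_test``.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if not 0 <= n_test < n:
        raise MetricsError("n_test must satisfy 0 <= n_test < n")
    classes, class_counts = np.unique(labels, return_counts=True)
    quotas = n_test * class_counts / n
    base = np.floor(quotas).astype(int)
    remainder = n_test - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    take = base.copy()
    take[order[:remainder]] += 1
    if np.any(class_counts - take <= 0) and n_test > 0:
        raise MetricsError("a class would be emptied from the training set")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c, k in zip(classes, take):
        members = np.where(labels == c)[0]
        test_idx.extend(rng.choice(members, size=k, replace=False))
    test = np.sort(np.array(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def monte_carlo_validate(
    labels,
    evaluate_split: Callable[[np.ndarray, np.ndarray, int], tuple[np.ndarray, np.ndarray]],
    n_iter: int = 1000,
    eval_fraction: float = 0.2,
    seed: int = 0,
    context: str = "monte_carlo",
) -> ValidationReport:
    """Leave-many-out validation: repeated stratified splits, cumulative metrics.

    ``evaluate_split(train_idx, eval_idx, iteration_seed)`` must refit the
    model under validation on the training indices and return
    ``(y_true, y_pred)`` for the evaluation indices.  Predictions accumulate
    over all iterations and the metrics are computed once on the pooled
    predictions.  Iteration seeds derive deterministically from ``seed``;
    a failed iteration is logged and skipped, and more than 5% failures
    aborts the validation.
    """
    labels = np.asarray(labels, dtype=object)
    n_eval = int(round(eval_fraction * labels.size))
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_iter) % (2**31)
    pooled_true: list = []
    pooled_pred: list = []
    failures = 0
    for it in range(n_iter):
        split_seed = int(child_seeds[2 * it])
        fit_seed = int(child_seeds[2 * it + 1])
        try:
            train_idx, eval_idx = stratified_split(labels, n_eval, split_seed)
            y_true, y_pred = evaluate_split(train_idx, eval_idx, fit_seed)
        except Exception as exc:  # noqa: BLE001 - per-iteration isolation is the point
            failures += 1
            warnings.warn(f"Monte Carlo iteration {it} failed: {exc}")
            if failures > 0.05 * n_iter:
                raise MetricsError(
                    f"more than 5% of Monte Carlo iterations failed ({failures}/{it + 1})"
                ) from exc
            continue
        pooled_true.extend(np.asarray(y_true, dtype=object))
        pooled_pred.extend(np.asarray(y_pred, dtype=object))
    return class_metrics(pooled_true, pooled_pred, context=context)
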