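"""Descriptor reduction (V-WSP) and genetic-algorithm variable subset selection.

V-WSP is an unsupervised filter that keeps a well-spread subset of
descriptors in correlation space: with distance 1 - |r|, it repeatedly picks
a seed descriptor, discards every descriptor within the exclusion radius
(i.e. with |r| at or above the threshold), and moves to the nearest
survivor.  Retained pairs therefore all satisfy |r| < threshold, and every
discarded descriptor is represented by a retained one at |r| >= threshold.

GA-VSS is a supervised wrapper: chromosomes are descriptor subsets, fitness
is the cross-validated non-error rate of the coupled classifier under the
venetian-blinds scheme, and elitist replacement keeps the best-so-far
fitness monotone non-decreasing across generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin

from .datasets import DescriptorTable
from .metrics import class_metrics
from .model_selection import venetian_blind_cv
from .plsda import PLSDAClassifier


# ---------------------------------------------------------------------------
# V-WSP


class VWSPReducer(SelectorMixin, BaseEstimator):
    """Correlation-threshold descriptor reduction (V-WSP).

    Parameters
    ----------
    threshold : float, default 0.95
        Absolute-correlation cutoff; a pair at or above it cannot both be
        retained.  At 1.0 only exact duplicates are removed.
    seed_rule : {'densest', 'first'}, default 'densest'
        First seed: the descriptor with the highest mean absolute
        correlation to all others ('densest'), or simply the first column.
        Ties break by lexicographic descriptor name.
    """

    def __init__(self, threshold: float = 0.95, seed_rule: str = "densest"):
        self.threshold = threshold
        self.seed_rule = seed_rule

    def fit(self, X, y=None, names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be a 2-D matrix with at least one column")
        p = X.shape[1]
        self.names_ = list(names) if names is not None else [f"x{j}" for j in range(p)]
        if X.std(axis=0).min() <= 0:
            raise ValueError("constant column present; clean the table first")
        if p == 1:
            self.support_ = np.ones(1, dtype=bool)
            self.n_features_in_ = 1
            return self
        R = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(R, 1.0)

        # lexicographic-name tie-break for every argmax over candidates
        def best(candidates: np.ndarray, scores: np.ndarray) -> int:
            top = scores.max()
            tied = candidates[scores >= top - 1e-15]
            return min(tied, key=lambda j: self.names_[j])

        alive = np.ones(p, dtype=bool)
        retained: list[int] = []
        if self.seed_rule == "densest":
            mean_r = (R.sum(axis=0) - 1.0) / (p - 1)
            seed = best(np.arange(p), mean_r)
        elif self.seed_rule == "first":
            seed = 0
        else:
            raise ValueError(f"unknown seed rule {self.seed_rule!r}")
        while True:
            retained.append(seed)
            alive[seed] = False
            # remove everything too close (|r| >= threshold) to the seed;
            # the 1e-12 slack keeps exact duplicates removable at threshold 1.0
            removed = alive & (R[seed] >= self.threshold - 1e-12)
            alive[removed] = False
            survivors = np.where(alive)[0]
            if survivors.size == 0:
                break
            seed = best(survivors, R[seed, survivors])
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[retained] = True
        self.n_features_in_ = p
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    @property
    def retained_names_(self) -> list[str]:
        return [n for n, keep in zip(self.names_, self.support_) if keep]


def vwsp_reduce(table: DescriptorTable, threshold: float = 0.95,
                seed_rule: str = "densest") -> list[str]:
    """Retained descriptor names after V-WSP reduction of a descriptor table."""
    reducer = VWSPReducer(threshold=threshold, seed_rule=seed_rule)
    reducer.fit(table.values, names=table.names)
    return reducer.retained_names_


# ---------------------------------------------------------------------------
# GA-VSS


@dataclass
class GaConfig:
    """Genetic-algorithm settings for variable subset selection."""

    population_size: int = 30
    n_generations: int = 100
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    max_chromosome_size: int = 15
    elitism: int = 1
    cv_groups: int = 5
    seed: int = 0
    prune: bool = True
    prune_se_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SelectionResult:
    """Outcome of a GA run: subset, fitness trace and final CV metrics."""

    retained_names: list[str]
    fitness_trace: list[float]
    cv_ner: float
    cv_sn: float
    cv_sp: float
    log: list[dict] = field(default_factory=list)
    stage1: dict | None = None


def _chromosome_fitness(X, y, columns: tuple[int, ...], estimator, cv_groups: int):
    y_pred = venetian_blind_cv(X[:, list(columns)], y, estimator, cv_groups)
    report = class_metrics(y, y_pred, context="cv")
    return report.ner, report.sn_sweet, report.sp_sweet


def _ner_standard_error(sn: float, sp: float, n_pos: int, n_neg: int) -> float:
    """Binomial standard error of NER = (Sn + Sp)/2."""
    return 0.5 * np.sqrt(sn * (1 - sn) / n_pos + sp * (1 - sp) / n_neg)


def _backward_prune(X, y, chromosome, evaluate, cfg: GaConfig):
    """One-standard-error backward elimination of the GA winner.

    Cross-validated NER on a fixed fold assignment is a noisy, discrete
    criterion that wrapper selection can overfit; the classical remedy is to
    prefer the most parsimonious model whose fitness stays within one
    standard error of the best.  Variables are removed greedily (the removal
    giving the highest NER first) while the pruned model's NER stays at or
    above best - prune_se_factor * SE.
    """
    ner, sn, sp = evaluate(chromosome)
    n_pos = max(int(np.sum(y == c)) for c in np.unique(y))
    n_neg = int(y.size) - n_pos
    floor = ner - cfg.prune_se_factor * _ner_standard_error(sn, sp, n_pos, n_neg)
    current = list(chromosome)
    while len(current) > 1:
        candidates = [tuple(c for c in current if c != j) for j in current]
        scored = [(evaluate(c)[0], c) for c in candidates]
        best_ner, best_candidate = max(scored, key=lambda t: t[0])
        if best_ner >= floor:
            current = list(best_candidate)
        else:
            break
    return tuple(current)


def ga_vss(
    table: DescriptorTable,
    y,
    cfg: GaConfig | None = None,
    estimator=None,
) -> SelectionResult:
    """GA descriptor-subset search maximizing cross-validated NER.

    ``estimator`` is the classifier the selection is coupled with (a
    :class:`~sweetgate.plsda.PLSDAClassifier` by default; an N3 classifier
    plugs in unchanged).  Deterministic under ``cfg.seed``.  Chromosomes
    whose fitness evaluation fails are discarded with a log entry.
    """
    cfg = cfg or GaConfig()
    estimator = estimator if estimator is not None else PLSDAClassifier(n_lv=1)
    X = table.values
    y = np.asarray(y, dtype=object)
    p = X.shape[1]
    max_size = min(cfg.max_chromosome_size, p)
    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple[int, ...], tuple[float, float, float]] = {}
    log: list[dict] = []

    def evaluate(columns: tuple[int, ...]):
        if columns in cache:
            return cache[columns]
        try:
            result = _chromosome_fitness(X, y, columns, estimator, cfg.cv_groups)
        except Exception as exc:  # noqa: BLE001 - bad chromosomes are discarded
            log.append({"event": "discarded", "columns": list(columns), "reason": str(exc)})
            result = (-np.inf, 0.0, 0.0)
        cache[columns] = result
        return result

    def random_chromosome() -> tuple[int, ...]:
        size = int(rng.integers(1, max_size + 1))
        return tuple(sorted(rng.choice(p, size=size, replace=False)))

    def cap(mask: np.ndarray) -> tuple[int, ...]:
        on = np.where(mask)[0]
        if on.size == 0:
            return random_chromosome()
        if on.size > max_size:
            on = rng.choice(on, size=max_size, replace=False)
        return tuple(sorted(on))

    population = [random_chromosome() for _ in range(cfg.population_size)]
    fitness = [evaluate(c)[0] for c in population]
    trace: list[float] = []
    for _ in range(cfg.n_generations):
        order = np.argsort(fitness)[::-1]
        elites = [population[i] for i in order[: cfg.elitism]]
        offspring: list[tuple[int, ...]] = list(elites)
        while len(offspring) < cfg.population_size:
            # binary tournament selection
            a, b = rng.integers(0, cfg.population_size, size=2)
            parent1 = population[a if fitness[a] >= fitness[b] else b]
            a, b = rng.integers(0, cfg.population_size, size=2)
            parent2 = population[a if fitness[a] >= fitness[b] else b]
            mask1 = np.zeros(p, dtype=bool)
            mask1[list(parent1)] = True
            if rng.random() < cfg.crossover_prob:
                mask2 = np.zeros(p, dtype=bool)
                mask2[list(parent2)] = True
                swap = rng.random(p) < 0.5
                child_mask = np.where(swap, mask2, mask1)
            else:
                child_mask = mask1.copy()
            flip = rng.random(p) < cfg.mutation_prob
            child_mask ^= flip
            offspring.append(cap(child_mask))
        population = offspring
        fitness = [evaluate(c)[0] for c in population]
        trace.append(float(np.max(fitness)))

    best_idx = int(np.argmax(fitness))
    best = population[best_idx]
    if cfg.prune:
        best = _backward_prune(X, y, best, evaluate, cfg)
    ner, sn, sp = evaluate(best)
    return SelectionResult(
        retained_names=[table.names[j] for j in best],
        fitness_trace=trace,
        cv_ner=float(ner),
        cv_sn=float(sn),
        cv_sp=float(sp),
        log=log,
    )


def rank_selection_results(results: list[SelectionResult]) -> SelectionResult:
    """Pick a final model by NER first, then the smallest |Sn - Sp| (balance)."""
    return max(results, key=lambda r: (r.cv_ner, -abs(r.cv_sn - r.cv_sp)))


def blockwise_selection(
    table: DescriptorTable,
    y,
    cfg: GaConfig | None = None,
    estimator=None,
) -> SelectionResult:
    """Two-stage GA-VSS over descriptor blocks.

    Stage 1 runs the GA inside every block of the table's block map; stage 2
    runs it again on the union of the stage-1 selections.  Empty blocks are
    skipped with a warning.  A table with a single block degenerates to a
    plain :func:`ga_vss` run with the same seed.
    """
    cfg = cfg or GaConfig()
    if table.block_of is None:
        raise ValueError("descriptor table has no block map")
    uncovered = [n for n in table.names if n not in table.block_of]
    if uncovered:
        raise ValueError(f"block map does not cover descriptor(s) {uncovered[:5]}")
    blocks: dict[str, list[str]] = {}
    for name in table.names:
        blocks.setdefault(table.block_of[name], []).append(name)
    if len(blocks) == 1:
        return ga_vss(table, y, cfg, estimator)
    stage1: dict[str, SelectionResult] = {}
    merged: list[str] = []
    seed_seq = np.random.SeedSequence(cfg.seed)
    block_seeds = seed_seq.generate_state(len(blocks)) % (2**31)
    for (label, names), block_seed in zip(sorted(blocks.items()), block_seeds):
        if not names:
            warnings.warn(f"block {label!r} is empty; skipped")
            continue
        sub_cfg = GaConfig(**{**cfg.__dict__, "seed": int(block_seed)})
        result = ga_vss(table.subset_columns(names), y, sub_cfg, estimator)
        stage1[label] = result
        merged.extend(result.retained_names)
    final = ga_vss(table.subset_columns(sorted(set(merged))), y, cfg, estimator)
    final.stage1 = {label: r.retained_names for label, r in stage1.items()}
    return final
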