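"""Multi-objective genetic feature selection (NSGA-II).

Wrapper-style feature selection over binary masks with two objectives:
minimize the number of selected variables and maximize the cross-validated
score of a wrapped classifier restricted to those variables. The search
is the elitist NSGA-II scheme — fast non-dominated sorting, crowding
distance, binary tournament selection, uniform crossover, per-bit
mutation — extended with annihilation (the worst fraction of each
generation is replaced by fresh random masks) and elite replacement
(archived best-ever individuals overwrite the worst offspring).

Every evaluated mask is cached, and the reported Pareto front is the
non-dominated set over *all* masks ever evaluated, so the front can only
improve across generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score

from stroketriage.cohort import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "GAConfig",
    "evaluate_individual",
    "non_dominated_sort",
    "crowding_distance",
    "next_generation",
    "ga_select",
    "pareto_front",
    "GeneticFeatureSelector",
]

_SCORING = {"recall": "recall", "precision": "precision", "f1": "f1", "auc": "roc_auc"}


@dataclass
class Individual:
    """A candidate feature subset with its two objective values."""

    mask: np.ndarray  # boolean over candidate variables, >= 1 bit set
    objectives: tuple[int, float] | None = None  # (n_selected, cv_score)
    rank: int | None = None
    crowding: float | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def cv_score(self) -> float:
        return float(self.objectives[1]) if self.objectives else float("nan")

    def key(self) -> bytes:
        return np.packbits(self.mask).tobytes()


@dataclass(frozen=True)
class GAConfig:
    """NSGA-II budget and operator rates.

    Defaults (population 40, 30 generations) are sized for desk-scale
    runs; raise them for exhaustive searches on small candidate sets.
    """

    population_size: int = 40
    generations: int = 30
    mutation_rate: float = 0.02
    crossover_rate: float = 0.9
    tournament_size: int = 2
    elite_count: int = 2
    annihilation_fraction: float = 0.1
    elite_replacement_count: int = 2
    cv_folds: int = 3
    scoring: str = "f1"
    seed: int = 0
    #: seed of the cross-validation folds used to score masks; kept separate
    #: from ``seed`` so the objective landscape is identical across search
    #: seeds and fronts from independent runs are comparable
    cv_seed: int = 0

    def validate(self) -> None:
        if self.tournament_size < 2:
            raise ValidationError("tournament_size must be >= 2")
        n_annihilate = int(np.ceil(self.annihilation_fraction * self.population_size))
        if self.elite_count + n_annihilate >= self.population_size:
            raise ValidationError(
                "elite_count + ceil(annihilation_fraction * population_size) "
                "must be smaller than population_size"
            )
        if self.scoring not in _SCORING:
            raise ValidationError(f"scoring must be one of {sorted(_SCORING)}")
        for name in ("mutation_rate", "crossover_rate", "annihilation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


def evaluate_individual(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    config: GAConfig,
) -> tuple[int, float]:
    """Objectives for one mask: (popcount, mean stratified k-fold CV score)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValidationError("mask must select at least one variable")
    if len(np.unique(y)) < 2:
        raise ValidationError("dataset must contain both classes")
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.cv_seed)
    scores = cross_val_score(
        clone(estimator), np.asarray(X)[:, mask], y, cv=cv, scoring=_SCORING[config.scoring]
    )
    return int(mask.sum()), float(np.mean(scores))


def _dominates(a: tuple[int, float], b: tuple[int, float]) -> bool:
    """a dominates b: no worse on both objectives, strictly better on one.

    First objective (selected count) is minimized, second (score) maximized.
    """
    return (a[0] <= b[0] and a[1] >= b[1]) and (a[0] < b[0] or a[1] > b[1])


def non_dominated_sort(points: Sequence[tuple[int, float]]) -> list[list[int]]:
    """Fast non-dominated sort; returns fronts as lists of point indices."""
    n = len(points)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(points[i], points[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif _dominates(points[j], points[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(front: Sequence[tuple[int, float]]) -> np.ndarray:
    """Crowding distance per point: boundary points infinite, interior
    points the sum over objectives of normalized neighbour gaps; a
    zero-range objective contributes nothing."""
    n = len(front)
    if n == 0:
        raise ValidationError("front must be non-empty")
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    pts = np.asarray(front, dtype=float)
    for k in range(pts.shape[1]):
        order = np.argsort(pts[:, k], kind="stable")
        lo, hi = pts[order[0], k], pts[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        rng = hi - lo
        if rng <= 0:
            continue
        for pos in range(1, n - 1):
            i = order[pos]
            if np.isinf(dist[i]):
                continue
            dist[i] += (pts[order[pos + 1], k] - pts[order[pos - 1], k]) / rng
    return dist


def _assign_ranks(population: list[Individual]) -> None:
    fronts = non_dominated_sort([ind.objectives for ind in population])
    for rank, front in enumerate(fronts):
        dists = crowding_distance([population[i].objectives for i in front])
        for d, i in zip(dists, front):
            population[i].rank = rank
            population[i].crowding = float(d)


def _sort_key(ind: Individual) -> tuple[int, float]:
    return (ind.rank, -ind.crowding)


def _tournament(population: list[Individual], size: int, rng: np.random.Generator) -> Individual:
    picks = rng.integers(0, len(population), size=size)
    return min((population[i] for i in picks), key=_sort_key)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, len(mask))] = True
    return mask


def _random_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    return _repair(rng.random(n) < 0.5, rng)


def next_generation(
    population: list[Individual],
    config: GAConfig,
    rng: np.random.Generator,
    archive: Sequence[Individual] = (),
) -> list[Individual]:
    """One generational step; population size is conserved.

    Elites are copied unchanged; the remainder is bred by tournament
    selection, uniform crossover and bit-flip mutation; the worst
    annihilation fraction of offspring is replaced by fresh random
    masks; archived elites then overwrite the worst offspring.
    Individuals must already carry ranks and crowding distances.
    """
    config.validate()
    pop = sorted(population, key=_sort_key)
    n = len(pop)
    n_feat = len(pop[0].mask)
    elites = [Individual(ind.mask.copy(), ind.objectives) for ind in pop[: config.elite_count]]

    offspring: list[Individual] = []
    while len(offspring) < n - config.elite_count:
        p1 = _tournament(pop, config.tournament_size, rng)
        p2 = _tournament(pop, config.tournament_size, rng)
        c1, c2 = p1.mask.copy(), p2.mask.copy()
        if rng.random() < config.crossover_rate:
            swap = rng.random(n_feat) < 0.5
            c1[swap], c2[swap] = p2.mask[swap], p1.mask[swap]
        for child in (c1, c2):
            if config.mutation_rate > 0:
                flips = rng.random(n_feat) < config.mutation_rate
                child ^= flips
            if len(offspring) < n - config.elite_count:
                offspring.append(Individual(_repair(child, rng)))

    # annihilation: refresh the worst offspring with random masks
    n_annihilate = min(int(np.ceil(config.annihilation_fraction * n)), len(offspring))
    for i in range(len(offspring) - n_annihilate, len(offspring)):
        offspring[i] = Individual(_random_mask(n_feat, rng))

    # elite replacement: archived best-ever individuals overwrite the tail
    pool = sorted(archive, key=lambda a: -a.objectives[1])[: config.elite_replacement_count]
    for i, arch in enumerate(pool):
        slot = len(offspring) - n_annihilate - 1 - i
        if 0 <= slot < len(offspring):
            offspring[slot] = Individual(arch.mask.copy(), arch.objectives)

    return elites + offspring


def pareto_front(individuals: Sequence[Individual]) -> list[Individual]:
    """Deduplicated non-dominated subset, sorted by ascending mask size."""
    seen: dict[bytes, Individual] = {}
    for ind in individuals:
        seen.setdefault(ind.key(), ind)
    unique = list(seen.values())
    fronts = non_dominated_sort([ind.objectives for ind in unique])
    best = [unique[i] for i in fronts[0]]
    # collapse ties: keep one representative per objective pair
    by_obj: dict[tuple[int, float], Individual] = {}
    for ind in sorted(best, key=lambda x: (x.objectives[0], -x.objectives[1])):
        by_obj.setdefault((ind.objectives[0], round(ind.objectives[1], 12)), ind)
    return sorted(by_obj.values(), key=lambda x: x.objectives[0])


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    config: GAConfig | None = None,
) -> tuple[list[Individual], list[dict]]:
    """Run the NSGA-II search; returns (final Pareto front, per-generation history).

    Deterministic given ``config.seed``. The returned front is the
    non-dominated set over every mask evaluated during the run.
    """
    config = config or GAConfig()
    config.validate()
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 candidate variables")
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, tuple[int, float]] = {}

    def evaluate(ind: Individual) -> None:
        key = ind.key()
        if key not in cache:
            cache[key] = evaluate_individual(ind.mask, X, y, estimator, config)
        ind.objectives = cache[key]

    evaluated: dict[bytes, Individual] = {}

    def remember(ind: Individual) -> None:
        evaluated.setdefault(ind.key(), Individual(ind.mask.copy(), ind.objectives))

    population = [Individual(_random_mask(X.shape[1], rng)) for _ in range(config.population_size)]
    history: list[dict] = []
    for gen in range(config.generations):
        for ind in population:
            evaluate(ind)
            remember(ind)
        _assign_ranks(population)
        front = pareto_front(list(evaluated.values()))
        history.append(
            {
                "generation": gen,
                "front_size": len(front),
                "best_score": max(ind.objectives[1] for ind in front),
                "evaluations": len(cache),
                "hypervolume": _hypervolume(front, X.shape[1]),
            }
        )
        if gen < config.generations - 1:
            population = next_generation(population, config, rng, archive=front)

    final_front = pareto_front(list(evaluated.values()))
    logger.info(
        "ga_select: %d generations, %d unique masks evaluated, front size %d",
        config.generations,
        len(cache),
        len(final_front),
    )
    return final_front, history


def _hypervolume(front: Sequence[Individual], n_features: int) -> float:
    """2-D hypervolume against the reference point (n_features + 1, score 0)."""
    pts = sorted((ind.objectives for ind in front), key=lambda p: p[0])
    hv, prev_count = 0.0, n_features + 1
    for count, score in sorted(pts, key=lambda p: -p[0]):
        hv += (prev_count - count) * max(score, 0.0)
        prev_count = count
    return hv


class GeneticFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping the NSGA-II search.

    Parameters mirror :class:`GAConfig`; ``estimator`` is the classifier
    whose cross-validated score forms the second objective. After
    ``fit``, ``front_`` holds the Pareto front, ``history_`` the
    per-generation log, and ``support_`` the chosen mask (the
    highest-scoring front member; ties broken toward fewer features).

    Examples
    --------
    >>> from sklearn.tree import DecisionTreeClassifier
    >>> sel = GeneticFeatureSelector(DecisionTreeClassifier(max_depth=2),
    ...                              population_size=20, generations=10, seed=0)
    >>> Xt = sel.fit_transform(X, y)  # doctest: +SKIP
    """

    def __init__(
        self,
        estimator: BaseEstimator,
        population_size: int = 40,
        generations: int = 30,
        mutation_rate: float = 0.02,
        crossover_rate: float = 0.9,
        tournament_size: int = 2,
        elite_count: int = 2,
        annihilation_fraction: float = 0.1,
        elite_replacement_count: int = 2,
        cv_folds: int = 3,
        scoring: str = "f1",
        seed: int = 0,
        cv_seed: int = 0,
    ) -> None:
        self.estimator = estimator
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.tournament_size = tournament_size
        self.elite_count = elite_count
        self.annihilation_fraction = annihilation_fraction
        self.elite_replacement_count = elite_replacement_count
        self.cv_folds = cv_folds
        self.scoring = scoring
        self.seed = seed
        self.cv_seed = cv_seed

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            crossover_rate=self.crossover_rate,
            tournament_size=self.tournament_size,
            elite_count=self.elite_count,
            annihilation_fraction=self.annihilation_fraction,
            elite_replacement_count=self.elite_replacement_count,
            cv_folds=self.cv_folds,
            scoring=self.scoring,
            seed=self.seed,
            cv_seed=self.cv_seed,
        )

    def fit(self, X, y):
        X_arr = np.asarray(X, dtype=float)
        self.feature_names_in_ = (
            np.asarray(X.columns) if hasattr(X, "columns") else None
        )
        self.n_features_in_ = X_arr.shape[1]
        self.front_, self.history_ = ga_select(X_arr, np.asarray(y), self.estimator, self._config())
        best = max(self.front_, key=lambda ind: (ind.objectives[1], -ind.objectives[0]))
        self.support_ = best.mask.copy()
        if self.feature_names_in_ is not None:
            self.selected_features_ = [
                str(n) for n, keep in zip(self.feature_names_in_, self.support_) if keep
            ]
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
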