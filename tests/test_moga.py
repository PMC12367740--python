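"""NSGA-II: dominance, crowding, operators, and search correctness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.tree import DecisionTreeClassifier

from stroketriage.cohort import ValidationError
from stroketriage.moga import (
    GAConfig,
    GeneticFeatureSelector,
    Individual,
    crowding_distance,
    evaluate_individual,
    ga_select,
    next_generation,
    non_dominated_sort,
    pareto_front,
)


def brute_force_fronts(points):
    """O(n^2) reference partition by repeated removal of non-dominated points."""

    def dominates(a, b):
        return a[0] <= b[0] and a[1] >= b[1] and (a[0] < b[0] or a[1] > b[1])

    remaining = list(range(len(points)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(points[j], points[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestNonDominatedSort:
    def test_single_point_single_front(self):
        assert non_dominated_sort([(2, 0.5)]) == [[0]]

    def test_worked_example(self):
        pts = [(1, 0.90), (2, 0.95), (3, 0.90)]
        fronts = non_dominated_sort(pts)
        assert sorted(fronts[0]) == [0, 1]
        assert fronts[1] == [2]

    def test_duplicates_share_front(self):
        fronts = non_dominated_sort([(2, 0.8), (2, 0.8)])
        assert sorted(fronts[0]) == [0, 1]

    @given(
        st.lists(
            st.tuples(st.integers(1, 10), st.floats(0, 1, allow_nan=False)),
            min_size=1,
            max_size=25,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, pts):
        got = [sorted(f) for f in non_dominated_sort(pts)]
        assert got == brute_force_fronts(pts)

    def test_partition_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(0)
        pts = list(zip(rng.integers(1, 20, 50).tolist(), rng.random(50).tolist()))
        fronts = non_dominated_sort(pts)
        flat = [i for f in fronts for i in f]
        assert sorted(flat) == list(range(50))


class TestCrowdingDistance:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1, 0.5)])))
        assert np.all(np.isinf(crowding_distance([(1, 0.5), (2, 0.6)])))

    def test_collinear_equally_spaced_middle_is_two(self):
        d = crowding_distance([(1, 0.2), (2, 0.4), (3, 0.6)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_zero_range_axis_contributes_nothing(self):
        d = crowding_distance([(1, 0.5), (2, 0.5), (3, 0.5)])
        assert d[1] == pytest.approx(1.0)  # only the count axis contributes


class TestEvaluateIndividual:
    def test_leaky_feature_scores_one(self, leak_fixture):
        X, y = leak_fixture
        mask = np.zeros(5, dtype=bool)
        mask[3] = True
        n_sel, score = evaluate_individual(
            mask, X, y, DecisionTreeClassifier(max_depth=1, random_state=0), GAConfig()
        )
        assert n_sel == 1 and score == 1.0

    def test_first_objective_is_popcount(self, leak_fixture):
        X, y = leak_fixture
        mask = np.array([1, 0, 1, 1, 0], dtype=bool)
        n_sel, _ = evaluate_individual(
            mask, X, y, DecisionTreeClassifier(random_state=0), GAConfig()
        )
        assert n_sel == 3

    def test_noise_features_near_chance(self):
        """Pure-noise masks score near the permutation-null level of the
        scorer (F1 of a coin-flipping tree on balanced labels)."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, 200)
        _, score = evaluate_individual(
            np.ones(4, dtype=bool),
            X,
            y,
            DecisionTreeClassifier(max_depth=1, random_state=0),
            GAConfig(),
        )
        null = []
        for rep in range(30):
            perm = rng.permutation(y)
            null.append(
                evaluate_individual(
                    np.ones(4, dtype=bool),
                    X,
                    perm,
                    DecisionTreeClassifier(max_depth=1, random_state=0),
                    GAConfig(),
                )[1]
            )
        assert np.quantile(null, 0.01) - 0.1 <= score <= np.quantile(null, 0.99) + 0.1

    def test_empty_mask_and_single_class_errors(self, leak_fixture):
        X, y = leak_fixture
        with pytest.raises(ValidationError, match="at least one"):
            evaluate_individual(np.zeros(5, dtype=bool), X, y, DecisionTreeClassifier(), GAConfig())
        with pytest.raises(ValidationError, match="both classes"):
            evaluate_individual(
                np.ones(5, dtype=bool), X, np.zeros_like(y), DecisionTreeClassifier(), GAConfig()
            )


def _evaluated_population(n, n_feat, rng):
    pop = []
    for _ in range(n):
        mask = rng.random(n_feat) < 0.5
        if not mask.any():
            mask[0] = True
        ind = Individual(mask)
        ind.objectives = (int(mask.sum()), float(rng.random()))
        pop.append(ind)
    from stroketriage.moga import _assign_ranks

    _assign_ranks(pop)
    return pop


class TestNextGeneration:
    def test_reproduction_only_copies_parents(self):
        rng = np.random.default_rng(0)
        pop = _evaluated_population(12, 6, rng)
        cfg = GAConfig(
            population_size=12, mutation_rate=0.0, crossover_rate=0.0, annihilation_fraction=0.0
        )
        parents = {ind.key() for ind in pop}
        child_keys = {ind.key() for ind in next_generation(pop, cfg, rng)}
        assert child_keys <= parents

    def test_elites_survive_unchanged(self):
        rng = np.random.default_rng(1)
        pop = _evaluated_population(12, 6, rng)
        cfg = GAConfig(population_size=12, elite_count=2)
        best = sorted(pop, key=lambda i: (i.rank, -i.crowding))[:2]
        out = next_generation(pop, cfg, rng)
        out_keys = [ind.key() for ind in out[:2]]
        assert [b.key() for b in best] == out_keys

    def test_population_size_conserved_and_no_empty_masks(self):
        rng = np.random.default_rng(2)
        pop = _evaluated_population(20, 8, rng)
        cfg = GAConfig(population_size=20, mutation_rate=0.2)
        for _ in range(50):
            for ind in pop:
                if ind.objectives is None:
                    ind.objectives = (ind.n_selected, float(rng.random()))
            from stroketriage.moga import _assign_ranks

            _assign_ranks(pop)
            pop = next_generation(pop, cfg, rng)
            assert len(pop) == 20
            assert all(ind.mask.any() for ind in pop)


@pytest.fixture(scope="module")
def oracle_front(ga_fixture):
    X, y = ga_fixture
    est = DecisionTreeClassifier(max_depth=2, random_state=0)
    cfg = GAConfig()
    objs = []
    for bits in itertools.product([0, 1], repeat=8):
        mask = np.array(bits, dtype=bool)
        if mask.any():
            objs.append(evaluate_individual(mask, X, y, est, cfg))
    fronts = non_dominated_sort(objs)
    return sorted({objs[i] for i in fronts[0]})


class TestGaSelect:
    def test_exhaustive_budget_matches_enumeration_oracle(self, ga_fixture, oracle_front):
        X, y = ga_fixture
        est = DecisionTreeClassifier(max_depth=2, random_state=0)
        front, history = ga_select(
            X, y, est, GAConfig(population_size=256, generations=12, seed=0)
        )
        assert sorted({ind.objectives for ind in front}) == oracle_front
        assert len(history) == 12

    def test_front_oracle_equal_across_seeds(self, ga_fixture, oracle_front):
        X, y = ga_fixture
        est = DecisionTreeClassifier(max_depth=2, random_state=0)
        histories = []
        for seed in (1, 2):
            front, history = ga_select(
                X, y, est, GAConfig(population_size=256, generations=12, seed=seed)
            )
            assert sorted({ind.objectives for ind in front}) == oracle_front
            histories.append([h["evaluations"] for h in history])
        assert histories[0] != histories[1]  # the search path differs

    def test_single_informative_variable_found_alone(self, leak_fixture):
        X, y = leak_fixture
        front, _ = ga_select(
            X,
            y,
            DecisionTreeClassifier(max_depth=1, random_state=0),
            GAConfig(population_size=64, generations=8, seed=3),
        )
        singles = [ind for ind in front if ind.n_selected == 1]
        assert singles and singles[0].mask[3]

    def test_hypervolume_non_decreasing(self, ga_fixture):
        X, y = ga_fixture
        _, history = ga_select(
            X,
            y,
            DecisionTreeClassifier(max_depth=2, random_state=0),
            GAConfig(population_size=30, generations=10, seed=4),
        )
        hv = [h["hypervolume"] for h in history]
        assert all(b >= a - 1e-12 for a, b in zip(hv, hv[1:]))

    def test_seeded_determinism(self, ga_fixture):
        X, y = ga_fixture
        est = DecisionTreeClassifier(max_depth=2, random_state=0)
        cfg = GAConfig(population_size=20, generations=5, seed=9)
        f1, h1 = ga_select(X, y, est, cfg)
        f2, h2 = ga_select(X, y, est, cfg)
        assert [i.objectives for i in f1] == [i.objectives for i in f2]
        assert h1 == h2


class TestGeneticFeatureSelector:
    def test_sklearn_selector_interface(self, leak_fixture):
        X, y = leak_fixture
        sel = GeneticFeatureSelector(
            DecisionTreeClassifier(max_depth=1, random_state=0),
            population_size=30,
            generations=6,
            seed=0,
        )
        Xt = sel.fit_transform(X, y)
        assert Xt.shape[0] == X.shape[0]
        assert sel.get_support().sum() == Xt.shape[1]
        assert sel.support_[3]  # the label-leak column must be selected

    def test_get_params_round_trip(self):
        sel = GeneticFeatureSelector(DecisionTreeClassifier(), generations=4)
        params = sel.get_params()
        assert params["generations"] == 4
        sel.set_params(generations=7)
        assert sel.generations == 7
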