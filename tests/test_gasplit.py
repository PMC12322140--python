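import numpy as np
import pytest

from oncofusion import (
    GAParams,
    SimConfig,
    SplitProblem,
    assemble_vectors,
    balance_penalty,
    build_recurrence_labels,
    build_survival_labels,
    cosine_distance,
    exhaustive_split_oracle,
    fitness_in,
    fitness_out,
    generate_cohort,
    problem_from_vectors,
    run_ga,
)


def _problem(X, labels=None, mode="in_distribution", test_fraction=0.2, alpha=None):
    n = X.shape[0]
    if labels is None:
        labels = np.full((n, 1), np.nan)
    return SplitProblem(X=X, patient_ids=[f"{i:03d}" for i in range(n)],
                        labels=labels, test_fraction=test_fraction,
                        alpha=alpha, mode=mode)


class TestCosineDistance:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_unit_vectors(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([-1.0, 0.0])) == 2.0

    def test_orthogonal_vectors(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 5.0])) == 1.0

    def test_zero_vector_convention(self):
        with pytest.warns(UserWarning):
            assert cosine_distance(np.zeros(3), np.ones(3)) == 1.0


class TestBalancePenalty:
    def test_matched_fractions_zero_penalty(self):
        labels = np.array([[1.0], [0.0], [1.0], [0.0]])
        assert balance_penalty(np.array([1, 0, 0, 1], bool), labels, alpha=3.0) == 0.0

    def test_all_positive_test_set(self):
        # d_all = (0.5, 0.5), test all-positive for both classes, alpha 1
        labels = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], float)
        mask = np.array([1, 1, 0, 0], bool)
        assert balance_penalty(mask, labels, alpha=1.0) == pytest.approx(1.0)

    def test_quarter_deviation_alpha_two(self):
        # d_all = (0.5, 0.5); test picks fractions (0.25, 0.75); alpha 2 -> 1.0
        lab = np.array([[1, 1], [1, 1], [1, 1], [1, 1],
                        [0, 0], [0, 0], [0, 0], [0, 0]], float)
        mask = np.zeros(8, bool)
        mask[[0, 4, 5, 6]] = True  # class-1 fraction 0.25
        lab[:, 1] = lab[::-1, 0]   # class-2 fraction becomes 0.75 on the mask
        assert balance_penalty(mask, lab, alpha=2.0) == pytest.approx(2 * (0.25 + 0.25))

    def test_missing_labels_excluded(self):
        labels = np.array([[1.0], [np.nan], [0.0], [np.nan]])
        mask = np.array([1, 1, 1, 0], bool)
        # labeled: patients 0, 2 -> d_all = 0.5; labeled in test: 0, 2 -> 0.5
        assert balance_penalty(mask, labels, alpha=5.0) == 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            balance_penalty(np.zeros(4, bool), np.zeros((4, 1)), alpha=1.0)


class TestFitness:
    def test_two_orthogonal_unit_points(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        prob = _problem(X, test_fraction=0.99, alpha=0.0)
        assert fitness_in(np.array([1, 1], bool), prob) == pytest.approx(2.0)

    def test_identical_test_points_zero(self):
        X = np.ones((3, 2))
        prob = _problem(X, test_fraction=0.99, alpha=0.0)
        assert fitness_in(np.ones(3, bool), prob) == pytest.approx(0.0)
        assert fitness_out(np.ones(3, bool), prob) == pytest.approx(0.0)

    def test_antipodal_pair_out(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        prob = _problem(X, test_fraction=0.99, alpha=0.0)
        assert fitness_out(np.array([1, 1], bool), prob) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instance(self, seed):
        """Random 8-point instances, N=3: engine values equal exhaustive
        nearest-neighbor / all-pairs computation via cosine_distance."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 4))
        mask = np.zeros(8, bool)
        mask[rng.choice(8, 3, replace=False)] = True
        prob = _problem(X, test_fraction=3 / 8, alpha=0.0)
        idx = np.flatnonzero(mask)
        nn_sum = sum(min(cosine_distance(X[i], X[j]) for j in idx if j != i)
                     for i in idx)
        pair_sum = sum(cosine_distance(X[i], X[j])
                       for a, i in enumerate(idx) for j in idx[a + 1:])
        assert fitness_in(mask, prob) == pytest.approx(nn_sum, abs=1e-9)
        assert fitness_out(mask, prob) == pytest.approx(pair_sum, abs=1e-9)

    def test_single_test_point_rejected(self):
        prob = _problem(np.eye(4), test_fraction=0.3)
        with pytest.raises(ValueError):
            fitness_in(np.array([1, 0, 0, 0], bool), prob)


class TestOracle:
    def test_planted_antipodal_pair_selected(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.0, 0.05, size=(4, 3)) + 1.0,
                       [[5.0, 0.0, 0.0], [-5.0, 0.0, 0.0]]])
        prob = _problem(X, mode="out_of_distribution", test_fraction=2 / 6, alpha=0.0)
        mask, _ = exhaustive_split_oracle(prob, 2)
        assert np.flatnonzero(mask).tolist() == [4, 5]

    def test_all_identical_ties_break_lexicographically(self):
        X = np.ones((4, 2))
        prob = _problem(X, mode="out_of_distribution", test_fraction=0.5, alpha=0.0)
        mask, _ = exhaustive_split_oracle(prob, 2)
        assert mask.tolist() == [False, False, True, True]

    def test_oracle_at_least_ga(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 5))
        labels = rng.integers(0, 2, size=(10, 2)).astype(float)
        for mode in ("in_distribution", "out_of_distribution"):
            prob = _problem(X, labels=labels, mode=mode)
            _, f_opt = exhaustive_split_oracle(prob, 2)
            res = run_ga(prob, GAParams(population_size=60, stagnation_limit=10,
                                        max_generations=50, mutation_rate=0.3, seed=1))
            assert f_opt >= res.best_fitness - 1e-12

    def test_too_large_instance_rejected(self):
        prob = _problem(np.random.default_rng(0).normal(size=(60, 3)))
        with pytest.raises(ValueError):
            exhaustive_split_oracle(prob, 20)


@pytest.fixture(scope="module")
def cohort_problem():
    cohort = generate_cohort(SimConfig(n_patients=100, seed=31))
    vs = assemble_vectors(cohort)
    rec = build_recurrence_labels(cohort)
    sur = build_survival_labels(cohort)
    labels = np.column_stack([rec.label_array(vs.patient_ids),
                              sur.label_array(vs.patient_ids)])
    return cohort, vs, labels


class TestRunGA:

    def test_partition_and_test_size(self, cohort_problem):
        cohort, vs, labels = cohort_problem
        prob = problem_from_vectors(vs, labels, test_fraction=0.2)
        res = run_ga(prob, GAParams(population_size=80, stagnation_limit=10,
                                    max_generations=60, mutation_rate=0.3, seed=0))
        assert sorted(res.train_ids + res.test_ids) == cohort.patient_ids
        assert not set(res.train_ids) & set(res.test_ids)
        assert len(res.test_ids) == round(0.2 * vs.complete.sum())

    def test_incomplete_patients_assigned_to_training(self, cohort_problem):
        _, vs, labels = cohort_problem
        prob = problem_from_vectors(vs, labels)
        res = run_ga(prob, GAParams(population_size=80, stagnation_limit=10,
                                    max_generations=60, mutation_rate=0.3, seed=0))
        incomplete = {p for p, c in zip(vs.patient_ids, vs.complete) if not c}
        assert incomplete <= set(res.train_ids)

    def test_trace_monotone_nondecreasing(self, cohort_problem):
        _, vs, labels = cohort_problem
        prob = problem_from_vectors(vs, labels, mode="out_of_distribution")
        res = run_ga(prob, GAParams(population_size=80, stagnation_limit=10,
                                    max_generations=60, mutation_rate=0.3, seed=4))
        trace = np.array(res.fitness_trace)
        assert (np.diff(trace) >= 0).all()

    def test_deterministic_under_seed(self, cohort_problem):
        _, vs, labels = cohort_problem
        prob = problem_from_vectors(vs, labels)
        params = GAParams(population_size=60, stagnation_limit=8,
                          max_generations=40, mutation_rate=0.3, seed=9)
        a = run_ga(prob, params)
        b = run_ga(prob, params)
        assert a.test_ids == b.test_ids and a.best_fitness == b.best_fitness
        assert a.fitness_trace == b.fitness_trace

    def test_in_dist_test_set_closer_to_train_distribution(self, cohort_problem):
        """In-distribution test points sit nearer the training distribution
        (mean cosine distance to the training centroid) than
        out-of-distribution ones, which load on the extremes."""
        _, vs, labels = cohort_problem
        params = GAParams(population_size=150, stagnation_limit=15,
                          max_generations=120, mutation_rate=0.3, seed=2)
        Xn = vs.X / np.linalg.norm(vs.X, axis=1, keepdims=True)
        idx = {p: i for i, p in enumerate(vs.patient_ids)}
        means = {}
        for mode in ("in_distribution", "out_of_distribution"):
            res = run_ga(problem_from_vectors(vs, labels, mode=mode), params)
            te = [idx[p] for p in res.test_ids]
            tr = [idx[p] for p in res.train_ids]
            centroid = Xn[tr].mean(axis=0)
            centroid /= np.linalg.norm(centroid)
            means[mode] = (1.0 - Xn[te] @ centroid).mean()
        assert means["in_distribution"] < means["out_of_distribution"]

    def test_infeasible_split_rejected(self):
        prob = _problem(np.eye(3), test_fraction=0.34)
        with pytest.raises(ValueError):
            run_ga(prob, GAParams(population_size=10))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GAParams(population_size=1)
        with pytest.raises(ValueError):
            GAParams(crossover_rate=1.5)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0))
    def test_penalty_bounds_and_linearity_in_alpha(seed, alpha):
        """0 <= penalty <= alpha*C, and the penalty is linear in alpha."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=(n, 2)).astype(float)
        mask = np.zeros(n, bool)
        mask[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        p1 = balance_penalty(mask, labels, alpha=1.0)
        pa = balance_penalty(mask, labels, alpha=alpha)
        assert 0.0 <= p1 <= 2.0
        assert pa == pytest.approx(alpha * p1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_cosine_distance_range_and_symmetry(seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=5), rng.normal(size=5)
        d = cosine_distance(u, v)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(cosine_distance(v, u))
        assert cosine_distance(3.0 * u, v) == pytest.approx(d, abs=1e-9)
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_default_alpha_scales_with_mode():
    X = np.random.default_rng(0).normal(size=(20, 3))
    prob_in = _problem(X, mode="in_distribution", test_fraction=0.2)
    prob_out = _problem(X, mode="out_of_distribution", test_fraction=0.2)
    n = prob_in.n_test
    assert prob_in.resolved_alpha() == n
    assert prob_out.resolved_alpha() == n * (n - 1) / 2
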