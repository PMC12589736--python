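from itertools import combinations

import numpy as np
import pytest
from scipy import stats as scipy_stats

from histofuse.aco_select import (ACOConfig, PheromoneState,
                                  construct_subset, default_subset_size,
                                  evaluate_subset, heuristic_importance,
                                  init_pheromone, run_aco, update_pheromone)
from histofuse.synthetic import PlantedFeatureProblem, generate_feature_problem


@pytest.fixture
def planted_small():
    prob = PlantedFeatureProblem(n_samples=60, n_features=8, n_informative=3,
                                 effect_size=5.0, n_classes=2, seed=0)
    return generate_feature_problem(prob)


class TestHeuristicImportance:
    def test_constant_feature_scores_zero(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 1.0
        y = np.repeat(["a", "b"], 15)
        imp = heuristic_importance(X, y)
        assert imp[2] == 0.0

    def test_label_indicator_beats_noise(self, rng):
        y = np.repeat(["a", "b"], 20)
        X = rng.normal(size=(40, 3))
        X[:, 0] = (y == "a").astype(float) + 0.01 * rng.normal(size=40)
        imp = heuristic_importance(X, y)
        assert imp[0] > 50 * max(imp[1], imp[2], 1e-9)

    def test_invariant_to_sample_permutation(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.repeat(["a", "b", "c"], 10)
        perm = rng.permutation(30)
        np.testing.assert_allclose(heuristic_importance(X, y),
                                   heuristic_importance(X[perm], y[perm]),
                                   atol=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            heuristic_importance(rng.normal(size=(10, 2)), np.repeat(["a"], 10))


class TestPheromoneState:
    def test_init_uniform_tau(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.repeat(["a", "b"], 10)
        state = init_pheromone(X, y, ACOConfig(initial_pheromone=0.1))
        np.testing.assert_allclose(state.tau, 0.1)
        assert len(state.tau) == len(state.eta) == 10

    def test_init_deterministic(self, rng):
        X = rng.normal(size=(20, 6))
        y = np.repeat(["a", "b"], 10)
        a = init_pheromone(X, y, ACOConfig())
        b = init_pheromone(X, y, ACOConfig())
        np.testing.assert_array_equal(a.tau, b.tau)
        np.testing.assert_array_equal(a.eta, b.eta)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            PheromoneState(tau=np.array([0.1, 0.0]), eta=np.array([1.0, 1.0]))


class TestConstructSubset:
    def test_uniform_when_exponents_zero(self):
        """alpha=gamma=0 must give uniform feature frequencies (chi-square)."""
        n, k, draws = 8, 2, 10_000
        state = PheromoneState(tau=np.linspace(0.1, 5.0, n),
                               eta=np.linspace(0.1, 5.0, n))
        cfg = ACOConfig(subset_size=k, pheromone_exponent=0.0,
                        importance_exponent=0.0)
        rng = np.random.default_rng(123)
        counts = np.zeros(n)
        for _ in range(draws):
            counts[construct_subset(state, cfg, rng)] += 1
        expected = draws * k / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert scipy_stats.chi2.sf(chi2, df=n - 1) > 0.01

    def test_dominant_pheromone_always_wins(self):
        tau = np.full(6, 1e-6)
        tau[3] = 1e6
        state = PheromoneState(tau=tau, eta=np.ones(6))
        cfg = ACOConfig(subset_size=1)
        rng = np.random.default_rng(5)
        hits = sum(construct_subset(state, cfg, rng)[0] == 3 for _ in range(1000))
        assert hits >= 999

    def test_full_subset_returns_all_features(self):
        state = PheromoneState(tau=np.ones(5), eta=np.zeros(5))
        cfg = ACOConfig(subset_size=5)
        out = construct_subset(state, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out, np.arange(5))

    def test_greedy_picks_top_weights(self):
        state = PheromoneState(tau=np.array([1.0, 3.0, 2.0, 0.5]),
                               eta=np.ones(4))
        cfg = ACOConfig(subset_size=2, greedy=True)
        out = construct_subset(state, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out, [1, 2])


class TestEvaluateSubset:
    def test_full_subset_equals_full_matrix_objective(self, planted_small):
        matrix, y, _ = planted_small
        full = evaluate_subset(matrix.values, y, range(matrix.n_features), seed=1)
        again = evaluate_subset(matrix.values, y, list(range(matrix.n_features)), seed=1)
        assert full == again

    def test_informative_subset_scores_perfectly(self, planted_small):
        matrix, y, truth = planted_small
        score = evaluate_subset(matrix.values, y, truth, seed=1)
        assert score == pytest.approx(1.0)

    def test_pure_noise_subset_near_chance_on_5_classes(self):
        prob = PlantedFeatureProblem(n_samples=200, n_features=10, n_informative=2,
                                     effect_size=8.0, n_classes=5, seed=3)
        matrix, y, truth = generate_feature_problem(prob)
        noise_cols = [j for j in range(10) if j not in set(truth)]
        scores = [evaluate_subset(matrix.values, y, noise_cols, seed=s)
                  for s in range(5)]
        assert abs(np.mean(scores) - 0.2) < 0.1

    def test_empty_subset_rejected(self, planted_small):
        matrix, y, _ = planted_small
        with pytest.raises(ValueError):
            evaluate_subset(matrix.values, y, [])


class TestUpdatePheromone:
    def test_no_evaporation_no_deposit_is_identity(self):
        state = PheromoneState(tau=np.array([0.3, 0.4]), eta=np.ones(2))
        cfg = ACOConfig(evaporation_rate=0.0)
        out = update_pheromone(state, [], cfg)
        np.testing.assert_allclose(out.tau, state.tau)

    def test_closed_form_single_deposit(self):
        tau0, rho, Q, s = 0.1, 0.2, 1.5, 0.8
        state = PheromoneState(tau=np.full(4, tau0), eta=np.ones(4))
        cfg = ACOConfig(evaporation_rate=rho, deposit_scale=Q,
                        initial_pheromone=tau0)
        out = update_pheromone(state, [([2], s)], cfg)
        assert out.tau[2] == pytest.approx((1 - rho) * tau0 + Q * s)
        np.testing.assert_allclose(np.delete(out.tau, 2), (1 - rho) * tau0)

    def test_tau_stays_positive_under_heavy_evaporation(self):
        state = PheromoneState(tau=np.full(3, 0.1), eta=np.ones(3))
        cfg = ACOConfig(evaporation_rate=0.5)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            state = update_pheromone(state, [([int(rng.integers(3))], 0.5)], cfg)
        assert np.all(state.tau > 0)

    def test_deposit_goes_to_iteration_best_only(self):
        state = PheromoneState(tau=np.full(4, 0.1), eta=np.ones(4))
        cfg = ACOConfig(evaporation_rate=0.0, deposit_scale=1.0)
        out = update_pheromone(state, [([0], 0.2), ([1], 0.9), ([2], 0.5)], cfg)
        assert out.tau[1] > out.tau[0] == out.tau[2] == out.tau[3]


class TestRunAco:
    def exhaustive_optimum(self, X, y, k, seed):
        return max(evaluate_subset(X, y, list(s), seed=seed)
                   for s in combinations(range(X.shape[1]), k))

    def test_finds_near_optimal_subset_on_planted_problem(self, planted_small):
        matrix, y, _ = planted_small
        cfg = ACOConfig(subset_size=3, n_ants=10, max_iters=50, seed=11,
                        error_threshold=0.0)
        result = run_aco(matrix.values, y, cfg)
        best = self.exhaustive_optimum(matrix.values, y, 3, seed=cfg.seed)
        assert result.best_score >= 0.95 * best

    def test_oracle_equivalence_over_seeded_problems(self):
        """>= 95% of the exhaustive-search optimum on 10 tiny seeded problems."""
        wins = 0
        for seed in range(10):
            prob = PlantedFeatureProblem(n_samples=40, n_features=7,
                                         n_informative=2, effect_size=3.0,
                                         n_classes=2, seed=seed)
            matrix, y, _ = generate_feature_problem(prob)
            cfg = ACOConfig(subset_size=2, n_ants=10, max_iters=50, seed=seed,
                            error_threshold=0.0)
            result = run_aco(matrix.values, y, cfg)
            best = self.exhaustive_optimum(matrix.values, y, 2, seed=seed)
            if result.best_score >= 0.95 * best:
                wins += 1
        assert wins == 10

    def test_full_subset_terminates_in_one_iteration(self, planted_small):
        matrix, y, _ = planted_small
        cfg = ACOConfig(subset_size=matrix.n_features, n_ants=3, max_iters=50,
                        seed=0)
        result = run_aco(matrix.values, y, cfg)
        assert len(result.score_trace) == 1
        assert result.best_subset == list(range(matrix.n_features))

    def test_reproducible_from_seed(self, planted_small):
        matrix, y, _ = planted_small
        cfg = ACOConfig(subset_size=3, n_ants=5, max_iters=10, seed=21)
        a = run_aco(matrix.values, y, cfg)
        b = run_aco(matrix.values, y, cfg)
        assert a.best_subset == b.best_subset
        assert a.score_trace == b.score_trace

    def test_score_trace_non_decreasing(self, planted_small):
        matrix, y, _ = planted_small
        cfg = ACOConfig(subset_size=3, n_ants=5, max_iters=20, seed=2,
                        error_threshold=0.0)
        trace = run_aco(matrix.values, y, cfg).score_trace
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_recovers_planted_informative_features(self):
        """Selected subsets are enriched for the planted columns in >=9/10 runs."""
        hits = 0
        for seed in range(10):
            prob = PlantedFeatureProblem(n_samples=80, n_features=12,
                                         n_informative=3, effect_size=2.0,
                                         n_classes=2, seed=100 + seed)
            matrix, y, truth = generate_feature_problem(prob)
            cfg = ACOConfig(subset_size=3, n_ants=8, max_iters=15, seed=seed,
                            error_threshold=0.0)
            result = run_aco(matrix.values, y, cfg)
            informative_fraction = len(set(result.best_subset) & set(truth)) / 3
            if informative_fraction > 3 / 12:
                hits += 1
        assert hits >= 9

    def test_published_subset_size_table(self):
        assert default_subset_size(("resnet50", "densenet169")) == 625
        assert default_subset_size(("densenet169", "mobilenet")) == 690
        assert default_subset_size(("resnet50", "mobilenet")) == 720
        assert default_subset_size(("resnet50", "densenet169", "mobilenet")) == 810
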