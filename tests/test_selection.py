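import itertools

import numpy as np
import pandas as pd
import pytest

from metconc.features import FeatureMatrix
from metconc.model import RidgeConfig, SVRConfig, loo_predictions, rmse
from metconc.selection import (
    GAConfig,
    VariableSubset,
    fitness_loo_rmse,
    ga_round,
    hill_climb_optimize,
    select_variables,
)

RIDGE = RidgeConfig(alpha=1e-3)


def _matrix(rng, n=20, k=8, informative=(0, 3), noise=0.1):
    X = rng.normal(size=(n, k))
    beta = np.zeros(k)
    for j, b in zip(informative, (1.0, -0.8)):
        beta[j] = b
    y = X @ beta + rng.normal(scale=noise, size=n)
    names = [f"v{j}" for j in range(k)]
    fm = FeatureMatrix(pd.DataFrame(X, columns=names), {c: "molecular" for c in names})
    return fm, y, [names[j] for j in informative]


def brute_force_loo_rmse(members, fm, y, regressor):
    """Oracle: assemble LOO predictions by explicit per-sample refits."""
    X = fm.frame[list(members)].to_numpy()
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        if isinstance(regressor, RidgeConfig):
            A = np.hstack([np.ones((n - 1, 1)), X[mask]])
            D = np.eye(X.shape[1] + 1)
            D[0, 0] = 0.0
            coef = np.linalg.solve(A.T @ A + regressor.alpha * D, A.T @ y[mask])
            preds[i] = coef[0] + X[i] @ coef[1:]
        else:
            from sklearn.svm import SVR

            est = SVR(kernel="rbf", gamma=regressor.gamma, epsilon=regressor.epsilon, C=regressor.cost)
            preds[i] = est.fit(X[mask], y[mask]).predict(X[i : i + 1])[0]
    return float(np.sqrt(np.mean((y - preds) ** 2)))


class TestFitness:
    def test_matches_brute_force_oracle(self, rng):
        fm, y, _ = _matrix(rng)
        for members in (["v0"], ["v0", "v3"], ["v1", "v2", "v5"]):
            assert fitness_loo_rmse(members, fm, y, RIDGE) == pytest.approx(
                brute_force_loo_rmse(members, fm, y, RIDGE), abs=1e-9
            )

    def test_svr_fitness_matches_brute_force(self, rng):
        fm, y, _ = _matrix(rng, n=12)
        cfg = SVRConfig(gamma=0.1, epsilon=0.05, cost=10.0)
        assert fitness_loo_rmse(["v0", "v3"], fm, y, cfg) == pytest.approx(
            brute_force_loo_rmse(["v0", "v3"], fm, y, cfg), abs=1e-9
        )

    def test_subset_ordering_matches_oracle(self, rng):
        fm, y, informative = _matrix(rng)
        good, bad = informative, ["v1", "v2"]
        assert fitness_loo_rmse(good, fm, y, RIDGE) < fitness_loo_rmse(bad, fm, y, RIDGE)
        assert brute_force_loo_rmse(good, fm, y, RIDGE) < brute_force_loo_rmse(bad, fm, y, RIDGE)

    def test_empty_subset_rejected(self, rng):
        fm, y, _ = _matrix(rng)
        with pytest.raises(ValueError):
            fitness_loo_rmse([], fm, y, RIDGE)


class TestGARound:
    def test_best_fitness_monotone_by_generation(self, rng):
        fm, y, _ = _matrix(rng, k=10)
        cfg = GAConfig(population_size=12, generations=15, seed=4)
        _, history = ga_round(fm.column_names, fm, y, cfg, RIDGE)
        assert all(a >= b - 1e-15 for a, b in zip(history, history[1:]))

    def test_deterministic_given_seed(self, rng):
        fm, y, _ = _matrix(rng, k=10)
        cfg = GAConfig(population_size=10, generations=8, seed=11)
        s1, h1 = ga_round(fm.column_names, fm, y, cfg, RIDGE)
        s2, h2 = ga_round(fm.column_names, fm, y, cfg, RIDGE)
        assert s1.member_names == s2.member_names and h1 == h2

    def test_no_variation_operators_returns_seed_chromosome(self, rng):
        fm, y, _ = _matrix(rng, k=6)
        cfg = GAConfig(population_size=6, generations=5, mutation_rate=0.0, seed=0)
        mask = np.array([True, False, True, False, False, False])
        subset, _ = ga_round(fm.column_names, fm, y, cfg, RIDGE, initial_population=[mask])
        assert subset.member_names == ["v0", "v2"]

    def test_tiny_pool_rejected(self, rng):
        fm, y, _ = _matrix(rng)
        with pytest.raises(ValueError):
            ga_round(["v0"], fm, y, GAConfig(), RIDGE)

    def test_recovers_informative_columns(self, rng):
        fm, y, informative = _matrix(rng, n=40, k=12, noise=0.1)
        cfg = GAConfig(population_size=25, generations=25, seed=2)
        subset, _ = ga_round(fm.column_names, fm, y, cfg, RIDGE)
        assert set(informative) <= set(subset.member_names)


class TestHillClimb:
    def test_exhaustive_optimum_returned_unchanged(self, rng):
        fm, y, _ = _matrix(rng, n=18, k=10)
        pool = fm.column_names
        # oracle: enumerate all 2^10 - 1 subsets
        best_members, best_fit = None, np.inf
        for r in range(1, len(pool) + 1):
            for combo in itertools.combinations(pool, r):
                fit = fitness_loo_rmse(list(combo), fm, y, RIDGE)
                if fit < best_fit:
                    best_members, best_fit = list(combo), fit
        start = VariableSubset(best_members, best_fit)
        out, trace = hill_climb_optimize(start, pool, fm, y, RIDGE)
        assert sorted(out.member_names) == sorted(best_members)
        assert out.fitness_rmse == pytest.approx(best_fit, abs=1e-12)
        assert len(trace) == 1  # no accepted move

    def test_perfect_predictor_column_dominates(self, rng):
        fm, y, _ = _matrix(rng, n=20, k=6, noise=0.3)
        frame = fm.frame.copy()
        frame["oracle_col"] = y  # zero-noise copy of the response
        fm2 = FeatureMatrix(frame, {**fm.origin.to_dict(), "oracle_col": "molecular"})
        start = VariableSubset(["v1"], fitness_loo_rmse(["v1"], fm2, y, RIDGE))
        out, _ = hill_climb_optimize(start, fm2.column_names, fm2, y, RIDGE)
        assert "oracle_col" in out.member_names
        assert out.fitness_rmse < 0.02

    def test_never_worse_than_input(self, rng):
        fm, y, _ = _matrix(rng, n=25, k=9)
        for start_cols in (["v0"], ["v4", "v5"], fm.column_names):
            start = VariableSubset(list(start_cols), fitness_loo_rmse(start_cols, fm, y, RIDGE))
            out, trace = hill_climb_optimize(start, fm.column_names, fm, y, RIDGE)
            assert out.fitness_rmse <= start.fitness_rmse + 1e-12
            assert trace["rmse_loo"].is_monotonic_decreasing

    def test_local_optimality_from_singletons(self, rng):
        fm, y, _ = _matrix(rng, n=20, k=8)
        pool = fm.column_names
        for name in pool[:4]:
            start = VariableSubset([name], fitness_loo_rmse([name], fm, y, RIDGE))
            out, _ = hill_climb_optimize(start, pool, fm, y, RIDGE)
            # oracle: check every one-move neighbour of the returned subset
            members = set(out.member_names)
            for col in pool:
                if col in members and len(members) > 1:
                    trial = sorted(members - {col})
                else:
                    trial = sorted(members | {col})
                assert fitness_loo_rmse(trial, fm, y, RIDGE) >= out.fitness_rmse - 1e-9


class TestFullSelection:
    def test_trace_schema_and_non_increasing_ga_counts(self, rng):
        fm, y, _ = _matrix(rng, n=30, k=10)
        cfg = GAConfig(population_size=10, generations=8, rounds=3, seed=5)
        subset, trace = select_variables(fm, y, cfg, RIDGE)
        assert list(trace.columns) == [
            "stage", "round", "m", "rmse_10fold", "q2_10fold", "rmse_loo", "q2_loo",
        ]
        ga_counts = trace.loc[trace["stage"].isin(["initial", "ga"]), "m"].tolist()
        assert all(a >= b for a, b in zip(ga_counts, ga_counts[1:]))
        assert subset.member_names == sorted(subset.member_names)

    def test_pipeline_deterministic(self, rng):
        fm, y, _ = _matrix(rng, n=30, k=10)
        cfg = GAConfig(population_size=10, generations=8, rounds=2, seed=5)
        s1, t1 = select_variables(fm, y, cfg, RIDGE)
        s2, t2 = select_variables(fm, y, cfg, RIDGE)
        assert s1.member_names == s2.member_names
        pd.testing.assert_frame_equal(t1, t2)
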