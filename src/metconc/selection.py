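"""Wrapper variable selection: chained GA rounds plus add/remove hill climb.

The candidate pool (all preprocessed descriptors) is reduced in three
stages:

1. Three chained genetic-algorithm rounds. Chromosomes are fixed-length
   bit vectors over the current pool; fitness is the leave-one-out RMSE
   of the downstream regressor restricted to the chromosome's columns
   (lower is better). Each round's winning subset becomes the next
   round's pool.
2. A steepest-descent hill climb over single-descriptor moves: every
   iteration evaluates all one-deletions from the current subset and all
   one-additions from the full preprocessed pool, accepts the best
   strictly RMSE-decreasing move, and stops at a local minimum.
3. Optionally (see :mod:`metconc.pipeline`) surviving pathway variables
   are collapsed into the single binary MPF descriptor.

Every accepted state is recorded in a selection trace with its variable
count and 10-fold / LOO RMSE and Q^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .model import (
    RegressorConfig,
    RidgeConfig,
    SVRConfig,
    cross_validate,
    loo_predictions,
    rmse,
)

__all__ = [
    "GAConfig",
    "VariableSubset",
    "fitness_loo_rmse",
    "ga_round",
    "hill_climb_optimize",
    "select_variables",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for one selection run.

    Defaults follow the reference procedure: population 100, 100
    generations, mutation rate 0.01, three chained rounds. Crossover
    rate, tournament size, elitism and the initial inclusion probability
    are standard GA equivalents left open by that procedure and exposed
    here.
    """

    population_size: int = 100
    generations: int = 100
    mutation_rate: float = 0.01
    rounds: int = 3
    seed: int = 0
    crossover_rate: float = 0.8
    tournament_size: int = 2
    elitism: int = 1
    init_inclusion: float = 0.4  # expected initial subset size as fraction of pool

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class VariableSubset:
    """A candidate descriptor subset with its LOO-RMSE fitness."""

    member_names: list[str]
    fitness_rmse: float

    def __post_init__(self) -> None:
        if self.fitness_rmse < 0:
            raise ValueError("fitness_rmse must be >= 0")
        self.member_names = list(self.member_names)


def fitness_loo_rmse(
    members: Sequence[str],
    matrix: FeatureMatrix,
    y: np.ndarray,
    regressor: RegressorConfig | None = None,
) -> float:
    """Leave-one-out RMSE of the configured regressor on a column subset."""
    if not len(members):
        raise ValueError("subset must be non-empty")
    regressor = regressor if regressor is not None else SVRConfig()
    X = matrix.frame[list(members)].to_numpy()
    preds = loo_predictions(X, np.asarray(y, dtype=float), regressor)
    return rmse(y, preds)


class _Evaluator:
    """Caches subset fitnesses keyed by the chromosome bit pattern."""

    def __init__(self, pool: list[str], matrix: FeatureMatrix, y, regressor: RegressorConfig):
        self.pool = pool
        self.X = matrix.frame[pool].to_numpy()
        self.y = np.asarray(y, dtype=float)
        self.regressor = regressor
        self.cache: dict[bytes, float] = {}
        self.n_evals = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        if not mask.any():
            fit = np.inf
        else:
            preds = loo_predictions(self.X[:, mask], self.y, self.regressor)
            fit = rmse(self.y, preds)
        self.cache[key] = fit
        self.n_evals += 1
        return fit


def ga_round(
    pool: Sequence[str],
    matrix: FeatureMatrix,
    y,
    cfg: GAConfig,
    regressor: RegressorConfig | None = None,
    seed: int | None = None,
    initial_population: Sequence[np.ndarray] | None = None,
) -> tuple[VariableSubset, list[float]]:
    """One GA round over ``pool``; returns the best subset and the
    per-generation best-so-far fitness history (non-increasing).

    ``initial_population`` (boolean masks over ``pool``) replaces the
    random Bernoulli initialisation when given; short lists are recycled.
    """
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError(f"pool must contain at least 2 descriptors, got {len(pool)}")
    regressor = regressor if regressor is not None else SVRConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    evaluate = _Evaluator(pool, matrix, y, regressor)
    p = len(pool)

    def random_chromosome() -> np.ndarray:
        mask = rng.random(p) < cfg.init_inclusion
        if not mask.any():
            mask[rng.integers(p)] = True
        return mask

    if initial_population is not None:
        population = [
            np.asarray(initial_population[i % len(initial_population)], dtype=bool).copy()
            for i in range(cfg.population_size)
        ]
    else:
        population = [random_chromosome() for _ in range(cfg.population_size)]
    fitnesses = [evaluate(m) for m in population]
    best_idx = int(np.argmin(fitnesses))
    best_mask, best_fit = population[best_idx].copy(), fitnesses[best_idx]
    history = [best_fit]

    for _ in range(cfg.generations):
        nxt: list[np.ndarray] = [best_mask.copy()] * cfg.elitism
        while len(nxt) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(cfg.population_size, size=cfg.tournament_size)
                winner = min(contenders, key=lambda i: fitnesses[i])
                parents.append(population[winner])
            if rng.random() < cfg.crossover_rate:
                take = rng.random(p) < 0.5  # uniform crossover
                child = np.where(take, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(p) < cfg.mutation_rate
            child = child ^ flip
            nxt.append(child)
        population = nxt
        fitnesses = [evaluate(m) for m in population]
        gen_best = int(np.argmin(fitnesses))
        if fitnesses[gen_best] < best_fit:
            best_fit = fitnesses[gen_best]
            best_mask = population[gen_best].copy()
        history.append(best_fit)

    members = [pool[i] for i in range(p) if best_mask[i]]
    return VariableSubset(members, best_fit), history


def _trace_row(
    stage: str,
    round_index: int,
    members: Sequence[str],
    matrix: FeatureMatrix,
    y,
    regressor: RegressorConfig,
    seed: int,
    loo_rmse: float | None = None,
) -> dict:
    X = matrix.frame[list(members)].to_numpy()
    y = np.asarray(y, dtype=float)
    tenfold = cross_validate(X, y, regressor, scheme="10fold", seed=seed)
    loo = cross_validate(X, y, regressor, scheme="loo", seed=seed)
    return {
        "stage": stage,
        "round": round_index,
        "m": len(members),
        "rmse_10fold": tenfold["rmse"],
        "q2_10fold": tenfold["q2"],
        "rmse_loo": loo["rmse"] if loo_rmse is None else loo_rmse,
        "q2_loo": loo["q2"],
    }


def hill_climb_optimize(
    current: VariableSubset,
    full_pool: Sequence[str],
    matrix: FeatureMatrix,
    y,
    regressor: RegressorConfig | None = None,
    trace_seed: int = 0,
    max_iterations: int = 1000,
) -> tuple[VariableSubset, pd.DataFrame]:
    """Steepest-descent add-one/remove-one optimization of a subset.

    Each iteration evaluates every single-descriptor deletion from the
    current subset and every single-descriptor addition from
    ``full_pool``; the best strictly LOO-RMSE-decreasing move is
    accepted (ties prefer the smaller subset, then the lexicographically
    first changed name). Terminates at a local minimum; the returned
    trace records the start state and every accepted state.
    """
    if not current.member_names:
        raise ValueError("current subset must be non-empty")
    full_pool = list(full_pool)
    missing = set(current.member_names) - set(full_pool)
    if missing:
        raise ValueError(f"current subset not contained in full pool: {sorted(missing)}")
    regressor = regressor if regressor is not None else SVRConfig()
    y = np.asarray(y, dtype=float)

    def fit_of(members: Sequence[str]) -> float:
        return fitness_loo_rmse(members, matrix, y, regressor)

    members = sorted(current.member_names)
    best = fit_of(members)
    trace = [
        _trace_row("hill_climb", 0, members, matrix, y, regressor, trace_seed, loo_rmse=best)
    ]
    for it in range(1, max_iterations + 1):
        candidates: list[tuple[float, int, str, list[str]]] = []
        if len(members) > 1:
            for name in members:
                trial = [m for m in members if m != name]
                candidates.append((fit_of(trial), len(trial), name, trial))
        for name in full_pool:
            if name not in members:
                trial = sorted(members + [name])
                candidates.append((fit_of(trial), len(trial), name, trial))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        fit, _, _, trial = candidates[0]
        if fit >= best:  # only strict improvements are accepted
            break
        members, best = trial, fit
        trace.append(
            _trace_row("hill_climb", it, members, matrix, y, regressor, trace_seed, loo_rmse=best)
        )
    return VariableSubset(members, best), pd.DataFrame(trace)


def select_variables(
    matrix: FeatureMatrix,
    y,
    cfg: GAConfig | None = None,
    regressor: RegressorConfig | None = None,
) -> tuple[VariableSubset, pd.DataFrame]:
    """Full selection pipeline: chained GA rounds, then hill climb.

    Returns the optimal subset and a trace table (one row per GA round
    and per accepted hill-climb state) with columns stage, round, m,
    rmse_10fold, q2_10fold, rmse_loo, q2_loo. Deterministic given
    (cfg.seed, data, config).
    """
    cfg = cfg or GAConfig()
    regressor = regressor if regressor is not None else SVRConfig()
    pool = list(matrix.column_names)
    y = np.asarray(y, dtype=float)
    round_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(cfg.seed).spawn(cfg.rounds)]

    rows = [_trace_row("initial", 0, pool, matrix, y, regressor, cfg.seed)]
    subset = VariableSubset(pool, rows[0]["rmse_loo"])
    for rnd in range(1, cfg.rounds + 1):
        if len(subset.member_names) < 2:
            break
        subset, _ = ga_round(subset.member_names, matrix, y, cfg, regressor, seed=round_seeds[rnd - 1])
        rows.append(
            _trace_row("ga", rnd, subset.member_names, matrix, y, regressor, cfg.seed, loo_rmse=subset.fitness_rmse)
        )
    subset, hc_trace = hill_climb_optimize(
        subset, pool, matrix, y, regressor=regressor, trace_seed=cfg.seed
    )
    hc_trace = hc_trace.iloc[1:]  # start state already traced as the last GA round
    hc_trace["round"] = range(cfg.rounds + 1, cfg.rounds + 1 + len(hc_trace))
    trace = pd.concat([pd.DataFrame(rows), hc_trace], ignore_index=True)
    return subset, trace


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    trace.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_subset(subset: VariableSubset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in subset.member_names:
            fh.write(name + "\n")
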