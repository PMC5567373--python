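"""epsilon-SVR concentration model with cross-validated quality metrics.

The response Y = -logC is regressed on a selected descriptor subset with
support-vector regression under an RBF kernel ``exp(-gamma * |u - v|^2)``.
Model quality is summarised by

* ``RMSE = sqrt(mean((Y_exp - Y_pred)^2))`` and
* ``Q^2  = 1 - sum((Y_exp - Y_pred)^2) / sum((Y_exp - Y_mean)^2)``,

computed once on the assembled out-of-fold prediction vector of a
cross-validation (10-fold or leave-one-out), plus the squared Pearson
correlation R^2 between fitted and observed values.

The public surface follows the statsmodels convention: build a
:class:`ConcentrationSVR` from data, call :meth:`~ConcentrationSVR.fit`,
and interrogate the returned :class:`SVRResults` (``summary()``,
``cross_validate()``, ``validate()``, ``applicability_domain()``).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "SVRConfig",
    "RidgeConfig",
    "ValidationReport",
    "TrialSummary",
    "rmse",
    "q2",
    "loo_predictions",
    "kfold_predictions",
    "cross_validate",
    "grid_search",
    "repeated_trials",
    "ConcentrationSVR",
    "SVRResults",
]

DEFAULT_GRID = {
    "gamma": (0.001, 0.01, 0.1, 1.0),
    "epsilon": (0.05, 0.1, 0.2, 0.4),
    "cost": (1.0, 11.0, 100.0),
}


@dataclass(frozen=True)
class SVRConfig:
    """RBF epsilon-SVR hyperparameters.

    Defaults are the tuned values of the reference concentration model
    (gamma=0.01, epsilon=0.20, cost=11).
    """

    gamma: float = 0.01
    epsilon: float = 0.20
    cost: float = 11.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.epsilon < 0 or self.cost <= 0:
            raise ValueError(f"invalid SVR config {self}")


@dataclass(frozen=True)
class RidgeConfig:
    """Ridge-regression stand-in regressor for desk-scale selection runs.

    A linear smoother with penalty ``alpha`` on the non-intercept
    coefficients; its leave-one-out residuals have the exact closed form
    ``e_i / (1 - h_ii)``, which makes wrapper-style variable selection
    orders of magnitude faster than refitting an SVR n times.
    """

    alpha: float = 1e-3

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


RegressorConfig = SVRConfig | RidgeConfig


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(y) != X.shape[0]:
        raise ValueError(f"length mismatch: X has {X.shape[0]} rows, y has {len(y)}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y; kernel matrix would be degenerate")
    return X, y


def rmse(y_exp: Sequence[float], y_pred: Sequence[float]) -> float:
    """Root-mean-square error between observed and predicted -logC."""
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def q2(y_exp: Sequence[float], y_pred: Sequence[float], y_mean: float | None = None) -> float:
    """Cross-validated coefficient ``1 - PRESS/TSS``; can be negative.

    ``y_mean`` defaults to the mean of ``y_exp`` over the evaluated set;
    pass the training mean explicitly for the training-mean convention on
    external test sets.
    """
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    mean = float(np.mean(a)) if y_mean is None else float(y_mean)
    tss = float(np.sum((a - mean) ** 2))
    if tss == 0.0:
        raise ValueError("y_exp is constant (zero total sum of squares); Q^2 undefined")
    return float(1.0 - np.sum((a - b) ** 2) / tss)


def pearson_r2(y_exp: Sequence[float], y_pred: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b)[0] ** 2)


def _make_estimator(config: RegressorConfig):
    if isinstance(config, SVRConfig):
        return SVR(kernel="rbf", gamma=config.gamma, epsilon=config.epsilon, C=config.cost)
    raise TypeError(f"no sklearn estimator for {type(config).__name__}")


def _ridge_fit(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Penalized LS with unpenalized intercept; returns (coef, hat diagonal)."""
    n, k = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    D = np.eye(k + 1)
    D[0, 0] = 0.0  # intercept unpenalized
    G = A.T @ A + alpha * D
    coef = np.linalg.solve(G, A.T @ y)
    # hat diagonal of the linear smoother A (A'A + aD)^{-1} A'
    h = np.einsum("ij,ji->i", A, np.linalg.solve(G, A.T))
    return coef, h


def _ridge_predict(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    return coef[0] + X @ coef[1:]


def loo_predictions(X: np.ndarray, y: np.ndarray, config: RegressorConfig) -> np.ndarray:
    """Leave-one-out predictions for every row.

    The SVR path performs the literal n refits; the ridge path uses the
    exact linear-smoother shortcut ``y_i - e_i / (1 - h_ii)``.
    """
    X, y = _check_xy(X, y)
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 samples for LOO, got {n}")
    if isinstance(config, RidgeConfig):
        coef, h = _ridge_fit(X, y, config.alpha)
        resid = y - _ridge_predict(coef, X)
        h = np.clip(h, None, 1 - 1e-12)
        return y - resid / (1.0 - h)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = _make_estimator(config)
        est.fit(X[mask], y[mask])
        preds[i] = est.predict(X[i : i + 1])[0]
    return preds


def kfold_predictions(
    X: np.ndarray, y: np.ndarray, config: RegressorConfig, n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Out-of-fold predictions from a seeded shuffled k-fold partition."""
    X, y = _check_xy(X, y)
    n = len(y)
    if n_folds > n:
        raise ValueError(f"{n_folds} folds but only {n} samples")
    preds = np.empty(n)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, hold_idx in kf.split(X):
        if isinstance(config, RidgeConfig):
            coef, _ = _ridge_fit(X[train_idx], y[train_idx], config.alpha)
            preds[hold_idx] = _ridge_predict(coef, X[hold_idx])
        else:
            est = _make_estimator(config)
            est.fit(X[train_idx], y[train_idx])
            preds[hold_idx] = est.predict(X[hold_idx])
    return preds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: RegressorConfig,
    scheme: str = "loo",
    seed: int = 0,
    n_folds: int = 10,
) -> dict:
    """RMSE and Q^2 from the assembled out-of-fold prediction vector."""
    if scheme == "loo":
        preds = loo_predictions(X, y, config)
    elif scheme in ("10fold", "kfold"):
        preds = kfold_predictions(X, y, config, n_folds=n_folds, seed=seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'loo' or '10fold'")
    return {"rmse": rmse(y, preds), "q2": q2(y, preds), "predictions": preds}


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence[float]] | None = None,
    scheme: str = "loo",
    seed: int = 0,
) -> SVRConfig:
    """Exhaustive hyperparameter search minimizing cross-validated RMSE.

    Ties are broken toward smaller cost, then smaller gamma, then smaller
    epsilon, so the result is deterministic.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if not all(len(v) for v in grid.values()):
        raise ValueError("grid must be non-empty for every parameter")
    best: tuple | None = None
    for cost, gamma, epsilon in itertools.product(
        sorted(grid.get("cost", (11.0,))),
        sorted(grid.get("gamma", (0.01,))),
        sorted(grid.get("epsilon", (0.20,))),
    ):
        cfg = SVRConfig(gamma=gamma, epsilon=epsilon, cost=cost)
        score = cross_validate(X, y, cfg, scheme=scheme, seed=seed)["rmse"]
        key = (score, cost, gamma, epsilon)
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1]


@dataclass
class ValidationReport:
    """Internal and external validation statistics of one fitted model."""

    n_train: int = 0
    n_features: int = 0
    r2_train: float = np.nan
    rmse_10fold: float = np.nan
    q2_10fold: float = np.nan
    rmse_loo: float = np.nan
    q2_loo: float = np.nan
    n_test: int = 0
    r2_test: float = np.nan
    rmse_test: float = np.nan
    q2_test: float = np.nan
    error_variance_loo: float = np.nan
    error_variance_test: float = np.nan

    def __post_init__(self) -> None:
        for name in ("rmse_10fold", "rmse_loo", "rmse_test"):
            v = getattr(self, name)
            if not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def to_json(self, path: str | Path) -> None:
        payload = {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass
class TrialSummary:
    """Mean +/- sd of validation metrics over repeated random splits."""

    n_trials: int
    per_trial: pd.DataFrame
    mean: pd.Series = field(init=False)
    sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        self.mean = self.per_trial.mean()
        self.sd = self.per_trial.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


class ConcentrationSVR:
    """epsilon-SVR model of -logC on a selected descriptor subset.

    Parameters
    ----------
    y : array-like
        Response (-logC) for the training rows.
    X : array-like or DataFrame
        Descriptor matrix restricted to the modelling subset. Values are
        used as-is (no internal scaling).
    config : SVRConfig, optional
        Hyperparameters; defaults to the reference tuned values.
    feature_names : sequence of str, optional
        Taken from DataFrame columns when omitted.
    """

    def __init__(self, y, X, config: SVRConfig | None = None, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else list(feature_names)
            X = X.to_numpy()
        self.X, self.y = _check_xy(X, y)
        if self.X.shape[0] < 3:
            raise ValueError("need at least 3 training rows")
        if self.X.shape[1] == 0:
            raise ValueError("descriptor subset is empty")
        self.config = config or SVRConfig()
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.X.shape[1])]
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        response: str = "neg_log_c",
        features: Sequence[str] | None = None,
        config: SVRConfig | None = None,
    ) -> "ConcentrationSVR":
        feats = [c for c in frame.columns if c != response] if features is None else list(features)
        return cls(frame[response].to_numpy(), frame[feats], config=config)

    def grid_search(self, grid=None, scheme: str = "loo", seed: int = 0) -> "ConcentrationSVR":
        """Return a new model with grid-searched hyperparameters."""
        cfg = grid_search(self.X, self.y, grid=grid, scheme=scheme, seed=seed)
        return ConcentrationSVR(self.y, self.X, config=cfg, feature_names=self.feature_names)

    def fit(self) -> "SVRResults":
        est = _make_estimator(self.config)
        est.fit(self.X, self.y)
        return SVRResults(self, est)


class SVRResults:
    """Results of a fitted :class:`ConcentrationSVR`."""

    def __init__(self, model: ConcentrationSVR, estimator: SVR):
        self.model = model
        self._est = estimator
        self.fittedvalues = estimator.predict(model.X)
        self.resid = model.y - self.fittedvalues

    # -- basic accessors ---------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.model.y)

    @property
    def k_features(self) -> int:
        return self.model.X.shape[1]

    @property
    def rsquared(self) -> float:
        """Squared Pearson correlation of fitted vs observed training values."""
        return pearson_r2(self.model.y, self.fittedvalues)

    def predict(self, X_new) -> np.ndarray:
        if isinstance(X_new, pd.DataFrame):
            X_new = X_new[self.model.feature_names].to_numpy()
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new.reshape(1, -1)
        return self._est.predict(X_new)

    # -- validation --------------------------------------------------------
    def cross_validate(self, scheme: str = "loo", seed: int = 0) -> dict:
        return cross_validate(self.model.X, self.model.y, self.model.config, scheme=scheme, seed=seed)

    def validate(
        self,
        X_test=None,
        y_test=None,
        seed: int = 0,
        q2_test_convention: str = "test_mean",
    ) -> ValidationReport:
        """Full internal (10-fold + LOO) and optional external validation."""
        tenfold = self.cross_validate("10fold", seed=seed)
        loo = self.cross_validate("loo", seed=seed)
        loo_err = self.model.y - loo["predictions"]
        report = ValidationReport(
            n_train=self.nobs,
            n_features=self.k_features,
            r2_train=self.rsquared,
            rmse_10fold=tenfold["rmse"],
            q2_10fold=tenfold["q2"],
            rmse_loo=loo["rmse"],
            q2_loo=loo["q2"],
            error_variance_loo=float(np.var(loo_err, ddof=1)),
        )
        if X_test is not None and y_test is not None and len(y_test):
            if isinstance(X_test, pd.DataFrame):
                X_test = X_test[self.model.feature_names].to_numpy()
            y_test = np.asarray(y_test, dtype=float)
            preds = self.predict(X_test)
            mean = None if q2_test_convention == "test_mean" else float(np.mean(self.model.y))
            report.n_test = len(y_test)
            report.r2_test = pearson_r2(y_test, preds)
            report.rmse_test = rmse(y_test, preds)
            report.q2_test = q2(y_test, preds, y_mean=mean)
            report.error_variance_test = float(np.var(y_test - preds, ddof=1))
        return report

    def applicability_domain(self, X_test=None, y_test=None) -> pd.DataFrame:
        """Leverage/standardized-residual table (Williams-plot data)."""
        from .domain import williams_data

        return williams_data(self, self.model.X, self.model.y, X_test, y_test)

    # -- presentation ------------------------------------------------------
    def summary(self, report: ValidationReport | None = None) -> str:
        cfg = self.model.config
        lines = [
            "epsilon-SVR concentration model (-logC)",
            "=" * 44,
            f"n_train:          {self.nobs}",
            f"k features:       {self.k_features}",
            f"gamma:            {cfg.gamma:g}",
            f"epsilon:          {cfg.epsilon:g}",
            f"cost (C):         {cfg.cost:g}",
            f"R^2 (train):      {self.rsquared:.3f}",
        ]
        if report is not None:
            lines += [
                f"10-fold RMSE/Q^2: {report.rmse_10fold:.3f} / {report.q2_10fold:.2f}",
                f"LOO RMSE/Q^2:     {report.rmse_loo:.3f} / {report.q2_loo:.2f}",
            ]
            if report.n_test:
                lines += [
                    f"test  n:          {report.n_test}",
                    f"test  R^2_p:      {report.r2_test:.3f}",
                    f"test  RMSE_p:     {report.rmse_test:.3f}",
                    f"test  Q^2_p:      {report.q2_test:.2f}",
                ]
        lines += ["features: " + ", ".join(self.model.feature_names)]
        return "\n".join(lines)

    # -- persistence (versioned JSON; no binary pickles) -------------------
    def save_json(self, path: str | Path) -> None:
        payload = {
            "format": "metconc-svr",
            "version": 1,
            "config": asdict(self.model.config),
            "feature_names": self.model.feature_names,
            "support_vectors": self._est.support_vectors_.tolist(),
            "dual_coef": self._est.dual_coef_.ravel().tolist(),
            "intercept": float(self._est.intercept_[0]),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @staticmethod
    def predict_from_json(path: str | Path, X_new) -> np.ndarray:
        """Predict with a JSON-persisted model (manual RBF expansion)."""
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "metconc-svr":
            raise ValueError(f"{path}: not a metconc SVR model file")
        sv = np.asarray(payload["support_vectors"], dtype=float)
        dual = np.asarray(payload["dual_coef"], dtype=float)
        gamma = float(payload["config"]["gamma"])
        if isinstance(X_new, pd.DataFrame):
            X_new = X_new[payload["feature_names"]].to_numpy()
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        d2 = ((X_new[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-gamma * d2) @ dual + payload["intercept"]


def repeated_trials(
    X,
    y,
    n_train: int,
    config: SVRConfig | None = None,
    n_trials: int = 20,
    seed: int = 0,
    grid=None,
) -> TrialSummary:
    """Repeat split/fit/validate over ``n_trials`` random partitions.

    Each trial draws its own train/test split from a seed spawned off
    ``seed``, optionally re-runs the hyperparameter grid search, and
    records training R^2, 10-fold and LOO RMSE/Q^2, and test R^2_p,
    RMSE_p, Q^2_p. The summary reports per-metric mean and sd.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X, y = _check_xy(X, y)
    n = len(y)
    if not (0 < n_train < n):
        raise ValueError(f"n_train must be in (0, {n})")
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(n_trials)
    for trial, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        idx = rng.permutation(n)
        tr, te = idx[:n_train], idx[n_train:]
        model = ConcentrationSVR(y[tr], X[tr], config=config)
        if grid is not None:
            model = model.grid_search(grid=grid, scheme="10fold", seed=trial)
        res = model.fit()
        rep = res.validate(X[te], y[te], seed=trial)
        rows.append(
            {
                "r2_train": rep.r2_train,
                "rmse_10fold": rep.rmse_10fold,
                "q2_10fold": rep.q2_10fold,
                "rmse_loo": rep.rmse_loo,
                "q2_loo": rep.q2_loo,
                "r2_test": rep.r2_test,
                "rmse_test": rep.rmse_test,
                "q2_test": rep.q2_test,
            }
        )
    return TrialSummary(n_trials=n_trials, per_trial=pd.DataFrame(rows))
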