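"""Leverage-based applicability domain and Williams-plot data.

The leverage of a query row ``x`` against the n x k training matrix
``X`` is ``h = x^T (X^T X)^{-1} x``; for training rows this is the hat
matrix diagonal, whose sum equals k for full-column-rank X. A sample is
inside the applicability domain iff its leverage does not exceed the
control threshold ``h* = 3k/n`` and its standardized residual (raw
residual divided by the training-residual RMSE) lies within +/-3.

X is the raw selected-descriptor matrix with no appended intercept
column. A rank-deficient X^T X raises an error naming the collinear
columns; ``pinv_fallback=True`` switches to a pseudo-inverse for
diagnostic use only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["h_star", "leverage", "leverages", "williams_data", "plot_williams"]


def h_star(k: int, n: int) -> float:
    """Control leverage threshold ``3k/n``."""
    if k <= 0 or n <= 0:
        raise ValueError("k and n must be positive")
    return 3.0 * k / n


def _xtx_inverse(X: np.ndarray, column_names: Sequence[str] | None, pinv_fallback: bool):
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < k:
        if pinv_fallback:
            return np.linalg.pinv(xtx)
        # name the columns loading on the null space
        _, s, vt = np.linalg.svd(xtx)
        tol = s[0] * max(n, k) * np.finfo(float).eps if len(s) else 0.0
        null = vt[s <= tol] if len(s) else vt
        names = column_names or [f"x{i}" for i in range(k)]
        flagged = sorted(
            {names[j] for row in np.atleast_2d(null) for j in np.argsort(-np.abs(row))[:2]}
        )
        raise np.linalg.LinAlgError(
            f"X^T X is singular (rank {rank} < {k}); collinear columns likely among: {flagged}"
        )
    return np.linalg.inv(xtx)


def leverages(
    X_train: np.ndarray,
    X_query: np.ndarray | None = None,
    column_names: Sequence[str] | None = None,
    pinv_fallback: bool = False,
) -> np.ndarray:
    """Leverage of every query row against the training matrix.

    With ``X_query=None`` returns the hat diagonal of the training rows.
    """
    X_train = np.asarray(X_train, dtype=float)
    inv = _xtx_inverse(X_train, column_names, pinv_fallback)
    Q = X_train if X_query is None else np.atleast_2d(np.asarray(X_query, dtype=float))
    return np.einsum("ij,jk,ik->i", Q, inv, Q)


def leverage(
    X_train: np.ndarray,
    x_query: Sequence[float],
    column_names: Sequence[str] | None = None,
    pinv_fallback: bool = False,
) -> float:
    """Leverage ``x^T (X^T X)^{-1} x`` of one query vector."""
    return float(leverages(X_train, np.atleast_2d(x_query), column_names, pinv_fallback)[0])


def williams_data(
    results,
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    ids: Sequence[str] | None = None,
    pinv_fallback: bool = False,
) -> pd.DataFrame:
    """Williams-plot table: leverage and standardized residual per sample.

    ``results`` is any object with a ``predict`` method fitted on the k
    selected variables. Residuals of both roles are standardized by the
    RMSE of the training residuals; ``in_domain`` flags samples with
    leverage <= h* = 3k/n and |standardized residual| <= 3.
    """
    feature_names = None
    if isinstance(X_train, pd.DataFrame):
        feature_names = list(X_train.columns)
        X_train = X_train.to_numpy()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n, k = X_train.shape
    thr = h_star(k, n)

    pred_train = np.asarray(results.predict(X_train), dtype=float)
    resid_train = y_train - pred_train
    scale = float(np.sqrt(np.mean(resid_train**2)))
    if scale == 0.0:
        scale = np.finfo(float).tiny  # perfect fit: residuals standardize to 0

    h_train = leverages(X_train, None, feature_names, pinv_fallback)
    frames = [
        pd.DataFrame(
            {
                "role": "train",
                "leverage": h_train,
                "std_residual": resid_train / scale,
            }
        )
    ]
    if X_test is not None and y_test is not None and len(np.atleast_1d(y_test)):
        if isinstance(X_test, pd.DataFrame):
            X_test = X_test.to_numpy()
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        y_test = np.asarray(y_test, dtype=float)
        resid_test = y_test - np.asarray(results.predict(X_test), dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "role": "test",
                    "leverage": leverages(X_train, X_test, feature_names, pinv_fallback),
                    "std_residual": resid_test / scale,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", list(ids) if ids is not None else [str(i) for i in range(len(out))])
    out["in_domain"] = (out["leverage"] <= thr) & (out["std_residual"].abs() <= 3.0)
    out.attrs["h_star"] = thr
    out.attrs["k"] = k
    out.attrs["n_train"] = n
    return out


def plot_williams(report: pd.DataFrame, path: str | Path, h_star_value: float | None = None) -> None:
    """Render the Williams plot with the h* and +/-3 sd guides."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thr = h_star_value if h_star_value is not None else report.attrs.get("h_star")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for role, marker, color in (("train", "o", "black"), ("test", "^", "magenta")):
        sub = report[report["role"] == role]
        ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, s=22,
                   facecolors="none", edgecolors=color, label=role)
    if thr is not None:
        ax.axvline(thr, linestyle="--", color="grey")
    ax.axhline(3.0, linestyle="--", color="grey")
    ax.axhline(-3.0, linestyle="--", color="grey")
    ax.set_xlabel("leverage $h_i$")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
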