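"""Successive Projections Algorithm (SPA).

SPA is a forward selection that minimizes collinearity: starting from a
seed column of the (mean-centered) calibration matrix, each step picks the
column with the largest component orthogonal to the span of the columns
already chosen.  Every start column and every chain length in a range is
scored by the cross-validated RMSE of an ordinary least-squares model on
the chain, and the globally best chain wins.  The chain order doubles as
the variables' importance order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import interleaved_folds


def _chain(Xc: np.ndarray, start: int, length: int, tol: float):
    """Projection chain from ``start``; stops early if no independent
    column remains.  Returns the (possibly shorter) chain."""
    n, p = Xc.shape
    proj = Xc.copy()
    selected = [start]
    active = np.ones(p, dtype=bool)
    active[start] = False
    for _ in range(1, length):
        v = proj[:, selected[-1]].copy()
        vv = float(v @ v)
        if vv <= tol**2:
            break
        proj -= np.outer(v, (v @ proj) / vv)
        norms = np.linalg.norm(proj, axis=0)
        norms[~active] = -1.0
        nxt = int(np.argmax(norms))  # ties -> lowest index
        if norms[nxt] <= tol:
            break
        selected.append(nxt)
        active[nxt] = False
    return np.array(selected)


def spa_chain(X, start: int, length: int) -> np.ndarray:
    """Ordered SPA chain of exactly ``length`` columns, starting at ``start``.

    Columns are mean-centered before projection.  Raises if the start
    column has zero norm or the chain cannot be extended to ``length``
    (all remaining columns lie in the span of the selected ones).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start < p:
        raise ValueError(f"start index {start} outside [0, {p})")
    if not 1 <= length <= p:
        raise ValueError(f"length must be in [1, {p}]")
    Xc = X - X.mean(axis=0)
    scale = float(np.linalg.norm(Xc, axis=0).max())
    tol = 1e-10 * max(scale, 1e-30)
    if np.linalg.norm(Xc[:, start]) <= tol:
        raise ValueError(f"start column {start} has zero norm after centering")
    chain = _chain(Xc, start, length, tol)
    if chain.size < length:
        raise ValueError(
            f"chain from column {start} exhausted after {chain.size} "
            f"linearly independent columns (requested {length})"
        )
    return chain


def _cv_mlr_rmse(X: np.ndarray, y: np.ndarray, folds: int):
    """Cross-validated RMSE of OLS-with-intercept; NaN if any fold is singular."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    fold_id = interleaved_folds(n, folds)
    preds = np.empty(n)
    for f in range(folds):
        test = fold_id == f
        train = ~test
        coef, _, rank, _ = np.linalg.lstsq(design[train], y[train], rcond=None)
        if rank < design.shape[1]:
            return np.nan
        preds[test] = design[test] @ coef
    return float(np.sqrt(np.mean((preds - y) ** 2)))


@dataclass(frozen=True)
class SPAResult:
    """Winning chain (importance order) and the full candidate-score table."""

    indices: np.ndarray  # selected columns, projection-chain order
    rmse: float  # cross-validated RMSE of the winning chain
    rmse_table: np.ndarray  # (n_variables, n_max); NaN where unscored
    start: int
    n_selected: int


def spa_select(X, y, n_min: int = 1, n_max: int | None = None,
               folds: int = 10) -> SPAResult:
    """Exhaustive SPA scan over start columns and chain lengths.

    Scores each candidate chain by the cross-validated RMSE of an ordinary
    least-squares fit; returns the global minimum (ties -> shorter chain,
    then lower start index).  Chains whose OLS fit is singular are skipped
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    fold_id = interleaved_folds(n, folds)
    min_train = min(n - int((fold_id == f).sum()) for f in range(folds))
    if n_max is None:
        n_max = min(p, 30, min_train - 1)
    if not 1 <= n_min <= n_max <= p:
        raise ValueError(f"need 1 <= n_min <= n_max <= {p}")
    Xc = X - X.mean(axis=0)
    scale = float(np.linalg.norm(Xc, axis=0).max())
    tol = 1e-10 * max(scale, 1e-30)
    table = np.full((p, n_max), np.nan)
    best = None  # (rmse, length, start, chain)
    for start in range(p):
        if np.linalg.norm(Xc[:, start]) <= tol:
            continue
        chain = _chain(Xc, start, n_max, tol)
        for m in range(n_min, chain.size + 1):
            score = _cv_mlr_rmse(X[:, chain[:m]], y, folds)
            if np.isnan(score):
                warnings.warn(
                    f"singular least-squares fit for chain start={start}, "
                    f"length={m}; skipped"
                )
                continue
            table[start, m - 1] = score
            # strict improvement beyond numerical noise, so that adding a
            # variable that changes nothing never displaces a shorter chain
            if best is None or score < best[0] - max(1e-12, 1e-9 * best[0]):
                best = (score, m, start, chain[:m].copy())
    if best is None:
        raise ValueError("no scorable SPA chain found")
    score, m, start, chain = best
    return SPAResult(indices=chain, rmse=score, rmse_table=table,
                     start=start, n_selected=m)


__all__ = ["SPAResult", "spa_chain", "spa_select"]
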