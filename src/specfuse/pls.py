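"""Single-response partial least squares (PLS1) and cross-validated RMSECV.

PLS1 is fitted by NIPALS.  The coefficient path for every component count
1..A is produced in one pass, which is what keeps RMSECV affordable inside
the variable-selection and model-update loops where thousands of sub-models
are cross-validated.

Cross-validation folds are assigned deterministically (sample i -> fold
i mod folds, in stored sample order) so identical inputs always yield
identical results; RMSECV pools out-of-fold residuals across all samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


def _pls1_path(X: np.ndarray, y: np.ndarray, max_components: int):
    """NIPALS PLS1 coefficient path.

    Returns
    -------
    B : ndarray, shape (A, p)
        B[a] is the regression coefficient vector using a+1 latent variables.
    intercepts : ndarray, shape (A,)
    n_effective : int
        Number of components actually extracted before the residual
        information was exhausted; rows beyond it repeat the last model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    A = int(max_components)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xd = X - x_mean
    yd = y - y_mean
    y_scale = max(1.0, float(np.linalg.norm(yd)))

    B = np.zeros((A, p))
    intercepts = np.full(A, y_mean)
    P = np.zeros((p, A))  # x-loadings
    R = np.zeros((p, A))  # W (P'W)^-1, so that B_a = R[:, :a+1] @ q[:a+1]
    b_cur = np.zeros(p)
    n_eff = 0
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _EPS * y_scale:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p_load = (Xd.T @ t) / tt
        q = float(yd @ t) / tt
        Xd -= np.outer(t, p_load)
        yd = yd - q * t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        P[:, a] = p_load
        R[:, a] = r
        b_cur = b_cur + q * r
        B[a] = b_cur
        intercepts[a] = y_mean - x_mean @ b_cur
        n_eff = a + 1
    if n_eff < A:  # pad: extra components add nothing
        B[n_eff:] = B[n_eff - 1] if n_eff > 0 else 0.0
        intercepts[n_eff:] = intercepts[n_eff - 1] if n_eff > 0 else y_mean
    return B, intercepts, n_eff


@dataclass(frozen=True)
class PLSRModel:
    """Fitted PLS1 regression model; prediction is affine in the spectrum."""

    n_components: int
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    n_effective: int

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept


def plsr_fit(X, y, n_components: int) -> PLSRModel:
    """Fit PLS1 with a fixed number of latent variables.

    At ``n_components`` equal to the rank of the centered X, the
    coefficients coincide with least squares on centered data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one y per row")
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress")
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components must be in [1, {limit}] for a {n}x{p} problem"
        )
    B, intercepts, n_eff = _pls1_path(X, y, n_components)
    a = n_components - 1
    return PLSRModel(
        n_components=n_components,
        coef=B[a],
        intercept=float(intercepts[a]),
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        n_effective=min(n_eff, n_components) or n_components,
    )


def interleaved_folds(n: int, folds: int) -> np.ndarray:
    """Deterministic fold assignment: sample i -> fold i mod folds."""
    return np.arange(n) % folds


@dataclass(frozen=True)
class CVResult:
    """RMSECV curve over candidate component counts."""

    components: np.ndarray
    rmsecv: np.ndarray
    best_n_components: int
    folds: int
    scheme: str = "interleaved"

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.best_n_components - 1])


def rmsecv(X, y, folds: int = 10, max_components: int = 20) -> CVResult:
    """Pooled cross-validated RMSE for component counts 1..A.

    A is capped at min(max_components, n_variables, smallest fold-train
    size - 1).  Residuals are pooled over all samples before taking the
    root mean square; the chosen component count is the curve's argmin
    (ties -> fewest components).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds n_samples ({n})")
    fold_id = interleaved_folds(n, folds)
    min_train = min(n - int((fold_id == f).sum()) for f in range(folds))
    A = max(1, min(int(max_components), p, min_train - 1))
    preds = np.empty((A, n))
    for f in range(folds):
        test = fold_id == f
        train = ~test
        B, intercepts, _ = _pls1_path(X[train], y[train], A)
        preds[:, test] = B @ X[test].T + intercepts[:, None]
    curve = np.sqrt(np.mean((preds - y[None, :]) ** 2, axis=1))
    best = int(np.argmin(curve)) + 1
    return CVResult(
        components=np.arange(1, A + 1),
        rmsecv=curve,
        best_n_components=best,
        folds=folds,
    )


def mean_predictor_rmsecv(y, folds: int = 10) -> float:
    """RMSECV of the intercept-only model (fold-train mean prediction)."""
    y = np.asarray(y, dtype=float)
    fold_id = interleaved_folds(y.size, folds)
    preds = np.empty_like(y)
    for f in range(folds):
        test = fold_id == f
        preds[test] = y[~test].mean()
    return float(np.sqrt(np.mean((preds - y) ** 2)))


__all__ = [
    "PLSRModel",
    "CVResult",
    "plsr_fit",
    "rmsecv",
    "interleaved_folds",
    "mean_predictor_rmsecv",
]
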