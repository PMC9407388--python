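"""Least-squares support vector machine regression with an RBF kernel.

LS-SVM replaces the SVM's inequality constraints with equalities, so the
fit reduces to one dense linear (KKT) system:

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma  ] [ alpha ] = [ y ],   K_ij = exp(-||x_i - x_j||^2 / sigma2)

Predictions are y(x) = sum_j alpha_j K(x, x_j) + b.  ``gamma`` is the
regularization weight (larger -> closer interpolation), ``sigma2`` the RBF
bandwidth in squared input units.  Hyperparameters are tuned on a
deterministic logarithmic grid by cross-validated RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

from .pls import interleaved_folds

DEFAULT_GAMMAS = tuple(10.0 ** np.arange(0, 7))
DEFAULT_SIGMA2S = tuple(10.0 ** np.arange(-2, 5))


def _rbf(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-cdist(A, B, metric="sqeuclidean") / sigma2)


@dataclass(frozen=True)
class LSSVMModel:
    """Fitted LS-SVM: all training rows act as support vectors."""

    X_train: np.ndarray
    alpha: np.ndarray
    b: float
    gamma: float
    sigma2: float
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    wavelengths: np.ndarray | None = None

    def _prep(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is not None:
            return (X - self.x_mean) / self.x_scale
        return X

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = _rbf(self._prep(X), self.X_train, self.sigma2)
        return K @ self.alpha + self.b

    def kkt_residual(self, y) -> float:
        """Max-norm residual of the KKT system this model should solve."""
        y = np.asarray(y, dtype=float)
        n = self.X_train.shape[0]
        K = _rbf(self.X_train, self.X_train, self.sigma2)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        sol = np.concatenate([[self.b], self.alpha])
        rhs = np.concatenate([[0.0], y])
        return float(np.max(np.abs(A @ sol - rhs)))

    def to_dict(self) -> dict:
        d = {
            "model": "lssvm-rbf",
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "b": self.b,
            "alpha": self.alpha.tolist(),
            "X_train": self.X_train.tolist(),
        }
        if self.x_mean is not None:
            d["x_mean"] = self.x_mean.tolist()
            d["x_scale"] = self.x_scale.tolist()
        if self.wavelengths is not None:
            d["wavelengths"] = self.wavelengths.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        return cls(
            X_train=np.array(d["X_train"], dtype=float),
            alpha=np.array(d["alpha"], dtype=float),
            b=float(d["b"]),
            gamma=float(d["gamma"]),
            sigma2=float(d["sigma2"]),
            x_mean=np.array(d["x_mean"]) if "x_mean" in d else None,
            x_scale=np.array(d["x_scale"]) if "x_scale" in d else None,
            wavelengths=np.array(d["wavelengths"]) if "wavelengths" in d else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=2)

    @classmethod
    def load(cls, path) -> "LSSVMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def lssvm_fit(X, y, gamma: float, sigma2: float, scale: bool = False,
              wavelengths=None) -> LSSVMModel:
    """Solve the LS-SVM KKT system by a dense direct solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    n = X.shape[0]
    if n < 2:
        raise ValueError("at least 2 training samples are required")
    x_mean = x_scale = None
    Xs = X
    if scale:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0, ddof=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
        Xs = (X - x_mean) / x_scale
    K = _rbf(Xs, Xs, sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    sol = solve(A, rhs)
    residual = float(np.max(np.abs(A @ sol - rhs)))
    if not np.isfinite(residual) or residual > 1e-6 * max(1.0, np.abs(y).max()):
        raise ArithmeticError(
            f"KKT system solved poorly (residual {residual:.3e}); "
            "the problem may be numerically singular"
        )
    return LSSVMModel(
        X_train=Xs, alpha=sol[1:], b=float(sol[0]), gamma=float(gamma),
        sigma2=float(sigma2), x_mean=x_mean, x_scale=x_scale,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


@dataclass(frozen=True)
class TuneResult:
    gamma: float
    sigma2: float
    cv_rmse: float
    surface: np.ndarray  # (len(gammas), len(sigma2s))
    gammas: tuple
    sigma2s: tuple


def lssvm_tune(X, y, gammas=None, sigma2s=None, folds: int = 10,
               scale: bool = False) -> TuneResult:
    """Grid search by deterministic cross-validated RMSE.

    Ties resolve to the smaller gamma, then the smaller sigma2 (the grids
    are scanned in ascending order with a strict-improvement rule).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gammas = tuple(DEFAULT_GAMMAS if gammas is None else gammas)
    sigma2s = tuple(DEFAULT_SIGMA2S if sigma2s is None else sigma2s)
    if not gammas or not sigma2s:
        raise ValueError("hyperparameter grids must be non-empty")
    n = X.shape[0]
    fold_id = interleaved_folds(n, folds)
    surface = np.empty((len(gammas), len(sigma2s)))
    best = None
    for gi, g in enumerate(sorted(gammas)):
        for si, s in enumerate(sorted(sigma2s)):
            preds = np.empty(n)
            for f in range(folds):
                test = fold_id == f
                model = lssvm_fit(X[~test], y[~test], g, s, scale=scale)
                preds[test] = model.predict(X[test])
            score = float(np.sqrt(np.mean((preds - y) ** 2)))
            surface[gi, si] = score
            if best is None or score < best[0]:
                best = (score, g, s)
    return TuneResult(gamma=best[1], sigma2=best[2], cv_rmse=best[0],
                      surface=surface, gammas=tuple(sorted(gammas)),
                      sigma2s=tuple(sorted(sigma2s)))


def lssvm_tune_fit(X, y, gammas=None, sigma2s=None, folds: int = 10,
                   scale: bool = False, wavelengths=None):
    """Convenience: tune on a grid, then fit on all samples."""
    tune = lssvm_tune(X, y, gammas=gammas, sigma2s=sigma2s, folds=folds, scale=scale)
    model = lssvm_fit(X, y, tune.gamma, tune.sigma2, scale=scale,
                      wavelengths=wavelengths)
    return model, tune


__all__ = [
    "LSSVMModel", "TuneResult", "lssvm_fit", "lssvm_tune", "lssvm_tune_fit",
    "DEFAULT_GAMMAS", "DEFAULT_SIGMA2S",
]
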