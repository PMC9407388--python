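"""Iteratively Retained Informative Variables (IRIV).

IRIV screens wavelengths by model population analysis: a binary matrix
draws hundreds of random variable subsets (rows); each row's PLS sub-model
is cross-validated, and each variable is judged by the paired contrast
between sub-models that include it and the same sub-models with it
removed.  Two statistics drive a four-way classification:

* DMEAN_i - mean RMSECV of including rows minus mean RMSECV of the same
  rows with variable i excluded (negative means the variable helps);
* P_i - two-sided Mann-Whitney U p-value between the two RMSECV samples.

Classification (alpha = 0.05): DMEAN<0 & P<alpha -> strongly informative,
DMEAN<0 & P>=alpha -> weakly informative, DMEAN>0 & P<alpha -> interfering,
DMEAN>0 & P>=alpha -> uninformative (DMEAN exactly 0 counts as weak).
Uninformative and interfering variables are dropped and the procedure
iterates; a final greedy backward elimination removes any variable whose
removal still lowers the full-model RMSECV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .pls import mean_predictor_rmsecv, rmsecv

STRONG = "strong"
WEAK = "weak"
UNINFORMATIVE = "uninformative"
INTERFERING = "interfering"


class IRIVError(RuntimeError):
    """Raised when iteration leaves no variable to retain."""


def bms_matrix(n_vars: int, n_rows: int, seed) -> np.ndarray:
    """Binary matrix sampling: each column holds exactly n_rows/2 ones.

    Columns are permuted independently; in the (vanishingly rare) event a
    row includes no variable at all, the whole matrix is redrawn.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be at least 1")
    if n_rows < 4 or n_rows % 2:
        raise ValueError("n_rows must be even and at least 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    column = np.zeros(n_rows, dtype=np.int8)
    column[: n_rows // 2] = 1
    matrix = np.column_stack([rng.permutation(column) for _ in range(n_vars)])
    # Repair any all-zero row by pulling a 1 down its column from a donor
    # row that keeps at least one variable; column sums stay exact and no
    # new zero rows can appear.
    for r in np.flatnonzero(matrix.sum(axis=1) == 0):
        donors = np.array([])
        for c in rng.permutation(n_vars):
            donors = np.flatnonzero(
                (matrix[:, c] == 1) & (matrix.sum(axis=1) >= 2)
            )
            if donors.size:
                break
        if donors.size == 0:
            raise RuntimeError("could not repair an empty row")
        donor = int(rng.choice(donors))
        matrix[r, c] = 1
        matrix[donor, c] = 0
    return matrix


def classify(dmean: float, p: float, alpha: float = 0.05) -> str:
    """Classify one variable from its (DMEAN, P) pair."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if dmean < 0:
        return STRONG if p < alpha else WEAK
    if dmean > 0:
        return INTERFERING if p < alpha else UNINFORMATIVE
    return WEAK  # boundary convention: a DMEAN of exactly 0 is kept as weak


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p; exact for small tie-free samples."""
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0  # all observations identical: no evidence of a shift
    pooled = np.concatenate([a, b])
    exact = a.size <= 8 and b.size <= 8 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


@dataclass(frozen=True)
class VariableDiagnostics:
    """Per-variable model-population statistics for one IRIV round."""

    variables: np.ndarray  # indices into the original design matrix
    dmean: np.ndarray
    p_value: np.ndarray
    classes: tuple

    def retained_mask(self) -> np.ndarray:
        return np.array([c in (STRONG, WEAK) for c in self.classes])


def _sub_rmsecv(X, y, cols, folds, max_components):
    if cols.size == 0:
        return mean_predictor_rmsecv(y, folds)
    return rmsecv(X[:, cols], y, folds=folds, max_components=max_components).best_rmsecv


def mpa_diagnostics(
    X, y, matrix: np.ndarray, folds: int = 10, max_components: int = 20,
    alpha: float = 0.05, variables=None,
) -> VariableDiagnostics:
    """Model population analysis over one binary inclusion matrix.

    For each variable i, the including rows' sub-model RMSECVs are paired
    against the same rows re-fitted with variable i removed (the matrix
    column zeroed), and DMEAN/P computed from the two samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    matrix = np.asarray(matrix)
    n_rows, n_vars = matrix.shape
    if n_vars != X.shape[1]:
        raise ValueError("matrix columns must match X columns")
    if variables is None:
        variables = np.arange(n_vars)
    row_cols = [np.flatnonzero(matrix[k]) for k in range(n_rows)]
    incl_rmsecv = np.array(
        [_sub_rmsecv(X, y, cols, folds, max_components) for cols in row_cols]
    )
    dmean = np.empty(n_vars)
    p_value = np.empty(n_vars)
    for i in range(n_vars):
        rows = np.flatnonzero(matrix[:, i])
        if rows.size == 0:
            raise ValueError(f"variable {i} is included in zero rows")
        excl = np.array(
            [
                _sub_rmsecv(X, y, row_cols[k][row_cols[k] != i], folds, max_components)
                for k in rows
            ]
        )
        incl = incl_rmsecv[rows]
        dmean[i] = incl.mean() - excl.mean()
        p_value[i] = _mann_whitney_p(incl, excl)
    classes = tuple(classify(d, p, alpha) for d, p in zip(dmean, p_value))
    return VariableDiagnostics(np.asarray(variables), dmean, p_value, classes)


@dataclass(frozen=True)
class IRIVResult:
    """Retention trace and final variable set of one IRIV run."""

    retained: tuple  # variable-index arrays after each iteration
    final: np.ndarray  # after backward elimination, ascending
    diagnostics: VariableDiagnostics  # from the last iteration
    n_iterations: int
    elimination_trace: tuple  # (removed variable, rmsecv after removal) pairs


def backward_eliminate(X, y, variables, folds=10, max_components=20):
    """Greedy best-first removal while it strictly lowers full-model RMSECV."""
    X = np.asarray(X, dtype=float)
    current = list(np.asarray(variables, dtype=int))
    trace = []
    best = _sub_rmsecv(X, y, np.array(current), folds, max_components)
    while len(current) > 1:
        scores = [
            _sub_rmsecv(
                X, y, np.array(current[:k] + current[k + 1 :]), folds, max_components
            )
            for k in range(len(current))
        ]
        k_best = int(np.argmin(scores))
        if scores[k_best] >= best:
            break
        best = scores[k_best]
        trace.append((current.pop(k_best), best))
    return np.array(sorted(current)), tuple(trace)


def iriv_select(
    X, y, n_rows: int = 500, max_iter: int = 8, alpha: float = 0.05,
    folds: int = 10, max_components: int = 20, seed: int = 0,
) -> IRIVResult:
    """Full IRIV run: iterative retention followed by backward elimination."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("IRIV needs at least 2 variables")
    current = np.arange(X.shape[1])
    retained = []
    diagnostics = None
    n_iter = 0
    for it in range(1, max_iter + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(it,))
        )
        matrix = bms_matrix(current.size, n_rows, rng)
        diagnostics = mpa_diagnostics(
            X[:, current], y, matrix, folds=folds,
            max_components=max_components, alpha=alpha, variables=current,
        )
        keep = diagnostics.retained_mask()
        n_iter = it
        if not keep.any():
            raise IRIVError(f"all variables eliminated at iteration {it}")
        dropped = int(current.size - keep.sum())
        current = current[keep]
        retained.append(current.copy())
        if dropped == 0 or current.size < 2:
            break
    final, elim_trace = backward_eliminate(
        X, y, current, folds=folds, max_components=max_components
    )
    return IRIVResult(
        retained=tuple(retained),
        final=final,
        diagnostics=diagnostics,
        n_iterations=n_iter,
        elimination_trace=elim_trace,
    )


__all__ = [
    "STRONG", "WEAK", "UNINFORMATIVE", "INTERFERING",
    "IRIVError", "bms_matrix", "classify", "mpa_diagnostics",
    "VariableDiagnostics", "IRIVResult", "backward_eliminate", "iriv_select",
]
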