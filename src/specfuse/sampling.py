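"""Kennard-Stone sample ordering and calibration/prediction splitting.

Kennard-Stone picks the two mutually farthest samples (Euclidean distance
in spectral space) first, then repeatedly adds the candidate whose minimum
distance to the already-selected set (Dm) is largest.  It yields a
representative, deterministic calibration set; ties break to the lowest
sample index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import ReferenceTable, SpectraSet


@dataclass(frozen=True)
class KSOrder:
    """Selection order and the Dm value recorded at each step."""

    indices: np.ndarray
    dm_trace: np.ndarray


def ks_order(X, n_select: int) -> KSOrder:
    """Greedy maximin (Kennard-Stone) ordering of ``n_select`` samples."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("at least 2 samples are required")
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}]")
    D = squareform(pdist(X, metric="euclidean"))
    # First pair: maximal pairwise distance; np.argmax on the row-major
    # flattened matrix gives the lexicographically smallest (i, j) tie-break.
    i, j = np.unravel_index(np.argmax(D), D.shape)
    first, second = (i, j) if i < j else (j, i)
    selected = [int(first), int(second)]
    dmax = float(D[first, second])
    dm_trace = [dmax, dmax]
    min_dist = np.minimum(D[first], D[second])
    min_dist[selected] = -np.inf
    for _ in range(2, n_select):
        nxt = int(np.argmax(min_dist))  # ties -> lowest index
        dm_trace.append(float(min_dist[nxt]))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return KSOrder(np.array(selected), np.array(dm_trace))


def ks_split(
    spectra: SpectraSet, reference: ReferenceTable, n_cal: int
) -> tuple[tuple[SpectraSet, ReferenceTable], tuple[SpectraSet, ReferenceTable]]:
    """Split into (calibration, prediction) by Kennard-Stone ordering.

    Calibration takes the first ``n_cal`` Kennard-Stone picks; the
    remainder (in original order) forms the prediction set.  Reference
    values are aligned to the spectra by sample id.
    """
    y = reference.aligned_to(spectra)
    n = spectra.n_samples
    if n_cal >= n:
        raise ValueError(
            f"n_cal ({n_cal}) must leave at least one prediction sample of {n}"
        )
    order = ks_order(spectra.reflectance, n_cal)
    cal_idx = order.indices
    mask = np.ones(n, dtype=bool)
    mask[cal_idx] = False
    pred_idx = np.flatnonzero(mask)
    cal = (
        spectra.select_samples(cal_idx),
        ReferenceTable(tuple(spectra.sample_ids[i] for i in cal_idx), y[cal_idx]),
    )
    pred = (
        spectra.select_samples(pred_idx),
        ReferenceTable(tuple(spectra.sample_ids[i] for i in pred_idx), y[pred_idx]),
    )
    return cal, pred


__all__ = ["KSOrder", "ks_order", "ks_split"]
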