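"""Offset-aware wavelength fusion and Euclidean-distance model updating.

This is the package's core method for keeping a calibration model valid
under a new measurement condition (e.g. a second cultivation mode):

1. **Wavelength fusion.** The characteristic wavelengths selected under
   each condition are merged.  Because absorption features drift slightly
   between conditions, any new-condition wavelength within a strict
   +/-``offset`` nm window (default 30 nm, open interval) of a
   base-condition wavelength is treated as a repeat of it and removed; the
   base wavelength always wins.  Surviving new wavelengths that collide
   with each other resolve in favour of the more important (earlier) one.

2. **Sample augmentation.** New-condition calibration samples are ranked
   by Kennard-Stone over the full-wavelength spectra; for each prefix size
   m the base calibration set plus the first m new samples is scored by
   the RMSECV of a PLS model restricted to the fused wavelengths.  The m
   minimizing RMSECV is kept, and an LS-SVM is recalibrated on the
   augmented set at the fused wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReferenceTable, SpectraSet
from .lssvm import LSSVMModel, lssvm_tune_fit
from .pls import rmsecv
from .sampling import ks_order

BASE = "base"
NEW = "new"
SHARED = "shared"


@dataclass(frozen=True)
class FusedWavelengthSet:
    """Fused characteristic wavelengths with provenance and removal log."""

    values: tuple  # nm, ascending
    provenance: tuple  # 'base' | 'new' | 'shared', aligned with values
    removed: tuple  # (removed value, anchor that displaced it) pairs
    offset: float

    def __len__(self) -> int:
        return len(self.values)

    def to_dict(self) -> dict:
        return {
            "offset_nm": self.offset,
            "values_nm": list(self.values),
            "provenance": list(self.provenance),
            "removed": [[v, a] for v, a in self.removed],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusedWavelengthSet":
        return cls(
            values=tuple(float(v) for v in d["values_nm"]),
            provenance=tuple(d["provenance"]),
            removed=tuple((float(v), float(a)) for v, a in d["removed"]),
            offset=float(d["offset_nm"]),
        )


def fuse_wavelengths(base, new, offset: float = 30.0) -> FusedWavelengthSet:
    """Merge two importance-ordered wavelength lists with offset dedup.

    ``base`` wavelengths are never removed.  A ``new`` wavelength is
    removed when it lies strictly within ``offset`` nm of a base
    wavelength (anchor = nearest base value; an exact match is recorded as
    shared) or of an earlier-surviving new wavelength.  ``new`` may be
    empty, which makes fusion idempotent: fuse(fused, []) == fused.
    """
    base = [float(v) for v in base]
    new = [float(v) for v in new]
    if not base:
        raise ValueError("base wavelength list must be non-empty")
    if offset <= 0:
        raise ValueError("offset must be positive")
    if any(v <= 0 for v in base + new):
        raise ValueError("wavelengths must be positive")
    base_values = sorted(set(base))
    shared = set()
    removed = []
    kept_new: list[float] = []
    for v in new:
        dists = [abs(v - b) for b in base_values]
        k = int(np.argmin(dists))
        if dists[k] == 0:
            shared.add(v)
            removed.append((v, v))
            continue
        if dists[k] < offset:
            removed.append((v, base_values[k]))
            continue
        conflicts = [u for u in kept_new if abs(v - u) < offset]
        if conflicts:
            anchor = min(conflicts, key=lambda u: abs(v - u))
            removed.append((v, anchor))
            continue
        kept_new.append(v)
    values = sorted(base_values + kept_new)
    prov = tuple(
        SHARED if v in shared else (BASE if v in base_values else NEW)
        for v in values
    )
    return FusedWavelengthSet(
        values=tuple(values), provenance=prov, removed=tuple(removed),
        offset=float(offset),
    )


@dataclass(frozen=True)
class UpdateTrace:
    """RMSECV as a function of the number of new-condition samples added."""

    rmsecv: np.ndarray  # entry m-1 <-> m added samples
    m_star: int  # chosen count (0 allowed only with allow_zero)
    ks_indices: np.ndarray  # Kennard-Stone order of the new samples
    rmsecv_zero: float | None = None  # base-only RMSECV, if computed

    @property
    def best_rmsecv(self) -> float:
        if self.m_star == 0:
            return float(self.rmsecv_zero)
        return float(self.rmsecv[self.m_star - 1])


def euclidean_update(
    base_cal: SpectraSet, base_y, new_cal: SpectraSet, new_y,
    fused: FusedWavelengthSet, folds: int = 10, max_components: int = 20,
    allow_zero: bool = False, force_m: int | None = None,
) -> tuple[SpectraSet, ReferenceTable, UpdateTrace]:
    """Augment the base calibration set with Kennard-Stone-ranked new samples.

    Distances for the ranking use the full-wavelength spectra; the RMSECV
    that selects the sample count is computed on the fused wavelengths
    (the final model's variables).  The augmented set always contains
    every base calibration sample; the returned spectra keep the full
    grid so any wavelength subset can still be modelled afterwards.
    """
    base_y = np.asarray(base_y, dtype=float)
    new_y = np.asarray(new_y, dtype=float)
    if new_cal.n_samples == 0:
        raise ValueError("new-condition calibration set is empty")
    if not np.array_equal(base_cal.wavelengths, new_cal.wavelengths):
        raise ValueError("base and new calibration sets must share one grid")
    cols = base_cal.wavelength_indices(fused.values)
    n_new = new_cal.n_samples
    if n_new >= 2:
        order = ks_order(new_cal.reflectance, n_select=n_new)
    else:  # a single candidate needs no ordering
        from .sampling import KSOrder

        order = KSOrder(np.array([0]), np.array([0.0]))
    base_Xf = base_cal.reflectance[:, cols]
    new_Xf = new_cal.reflectance[:, cols]
    trace = np.empty(n_new)
    for m in range(1, n_new + 1):
        idx = order.indices[:m]
        Xa = np.vstack([base_Xf, new_Xf[idx]])
        ya = np.concatenate([base_y, new_y[idx]])
        trace[m - 1] = rmsecv(Xa, ya, folds=folds,
                              max_components=max_components).best_rmsecv
    zero = None
    if allow_zero or force_m == 0:
        zero = rmsecv(base_Xf, base_y, folds=folds,
                      max_components=max_components).best_rmsecv
    if force_m is not None:
        if not 0 <= force_m <= n_new:
            raise ValueError(f"force_m must be in [0, {n_new}]")
        m_star = int(force_m)
    else:
        m_star = int(np.argmin(trace)) + 1  # ties -> smallest m
        if allow_zero and zero <= trace.min():
            m_star = 0
    chosen = order.indices[:m_star]
    aug = SpectraSet(
        base_cal.sample_ids + tuple(new_cal.sample_ids[i] for i in chosen),
        base_cal.wavelengths,
        np.vstack([base_cal.reflectance, new_cal.reflectance[chosen]]),
    )
    aug_y = ReferenceTable(aug.sample_ids,
                           np.concatenate([base_y, new_y[chosen]]))
    return aug, aug_y, UpdateTrace(rmsecv=trace, m_star=m_star,
                                   ks_indices=order.indices, rmsecv_zero=zero)


def recalibrate(
    augmented: SpectraSet, augmented_y, fused: FusedWavelengthSet,
    gammas=None, sigma2s=None, folds: int = 10, scale: bool = False,
) -> LSSVMModel:
    """Tune and fit an LS-SVM on the augmented set at the fused wavelengths."""
    y = (
        augmented_y.aligned_to(augmented)
        if isinstance(augmented_y, ReferenceTable)
        else np.asarray(augmented_y, dtype=float)
    )
    cols = augmented.wavelength_indices(fused.values)
    model, _ = lssvm_tune_fit(
        augmented.reflectance[:, cols], y, gammas=gammas, sigma2s=sigma2s,
        folds=folds, scale=scale, wavelengths=np.asarray(fused.values),
    )
    return model


__all__ = [
    "BASE", "NEW", "SHARED",
    "FusedWavelengthSet", "UpdateTrace",
    "fuse_wavelengths", "euclidean_update", "recalibrate",
]
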