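"""Spectral matrix and reference-table containers and delimited-text I/O.

The on-disk dialect is a plain CSV whose first column is ``sample_id`` and
whose remaining column headers are wavelengths in nm.  Reference tables are
two-column CSVs (``sample_id``, ``ssc``).  Wavelength grids are strictly
increasing; reflectance is nominally in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class SpectraParseError(ValueError):
    """Base class for malformed spectral files."""


class NonMonotonicWavelengthError(SpectraParseError):
    """Wavelength headers are not strictly increasing."""


class DuplicateSampleIdError(SpectraParseError):
    """Two rows carry the same sample id."""


class RaggedRowError(SpectraParseError):
    """Rows have inconsistent field counts or missing values."""


@dataclass(frozen=True)
class SpectraSet:
    """A set of reflectance spectra on a common wavelength grid.

    Attributes
    ----------
    sample_ids : tuple of str
        Unique identifiers, one per row of ``reflectance``.
    wavelengths : ndarray, shape (p,)
        Strictly increasing wavelengths in nm.
    reflectance : ndarray, shape (n, p)
        Unitless reflectance, nominally in [0, 1].
    """

    sample_ids: tuple
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 2:
            raise ValueError("reflectance must be a 2-D matrix")
        if len(ids) != r.shape[0]:
            raise ValueError(
                f"{len(ids)} sample ids but {r.shape[0]} spectra rows"
            )
        if w.ndim != 1 or w.size != r.shape[1]:
            raise ValueError(
                f"{w.size} wavelengths but {r.shape[1]} spectra columns"
            )
        if len(set(ids)) != len(ids):
            raise DuplicateSampleIdError("sample ids are not unique")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise NonMonotonicWavelengthError(
                "wavelengths must be strictly increasing"
            )
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance contains non-finite values")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def select_samples(self, indices) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            tuple(self.sample_ids[i] for i in idx),
            self.wavelengths,
            self.reflectance[idx],
        )

    def select_wavelengths(self, indices) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.sample_ids, self.wavelengths[idx], self.reflectance[:, idx])

    def wavelength_indices(self, values: Sequence[float], tol: float = 1e-6) -> np.ndarray:
        """Map nm values to column indices; raise if any value is absent."""
        out = np.empty(len(values), dtype=int)
        for k, v in enumerate(values):
            hits = np.flatnonzero(np.abs(self.wavelengths - float(v)) <= tol)
            if hits.size == 0:
                raise ValueError(f"wavelength {v} nm not on the grid")
            out[k] = hits[0]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance, columns=[str(w) for w in self.wavelengths])
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class ReferenceTable:
    """Reference analyte values (soluble solids content, % by refractometry)."""

    sample_ids: tuple
    values: np.ndarray = field(default=None)

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(ids):
            raise ValueError("one reference value per sample id is required")
        if len(set(ids)) != len(ids):
            raise DuplicateSampleIdError("sample ids are not unique")
        if not np.all(v > 0):
            raise ValueError("reference SSC values must be positive")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", v)

    def select(self, indices) -> "ReferenceTable":
        idx = np.asarray(indices, dtype=int)
        return ReferenceTable(tuple(self.sample_ids[i] for i in idx), self.values[idx])

    def aligned_to(self, spectra: SpectraSet) -> np.ndarray:
        """Return values reordered to match ``spectra.sample_ids`` one-to-one."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in spectra.sample_ids if s not in pos]
        if missing:
            raise ValueError(f"reference values missing for samples {missing[:5]}")
        return self.values[[pos[s] for s in spectra.sample_ids]]


def write_spectra(spectra: SpectraSet, path) -> None:
    # repr() emits the shortest digit string that round-trips the float
    spectra.to_dataframe().to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_spectra(path) -> SpectraSet:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise RaggedRowError(f"{path}: rows have inconsistent field counts") from exc
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise SpectraParseError(
            f"{path}: first column must be 'sample_id' followed by nm headers"
        )
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-numeric wavelength header") from exc
    values = df.iloc[:, 1:]
    if values.isna().any().any():
        raise RaggedRowError(f"{path}: missing values (short rows?)")
    try:
        matrix = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-numeric reflectance value") from exc
    return SpectraSet(tuple(df["sample_id"].astype(str)), wavelengths, matrix)


def write_reference(table: ReferenceTable, path) -> None:
    pd.DataFrame({"sample_id": list(table.sample_ids), "ssc": table.values}).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def read_reference(path) -> ReferenceTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["sample_id", "ssc"]:
        raise SpectraParseError(f"{path}: expected columns sample_id,ssc")
    if df["ssc"].isna().any():
        raise RaggedRowError(f"{path}: missing reference values")
    return ReferenceTable(tuple(df["sample_id"].astype(str)), df["ssc"].to_numpy(float))


def trim_range(spectra: SpectraSet, low: float, high: float) -> SpectraSet:
    """Restrict to wavelengths in the closed interval [low, high].

    The closed interval is what makes a 1 nm grid trimmed to 450-2400 nm
    contain exactly 1951 channels.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be below high ({high})")
    mask = (spectra.wavelengths >= low) & (spectra.wavelengths <= high)
    if not mask.any():
        raise ValueError(f"no wavelengths in [{low}, {high}]")
    return spectra.select_wavelengths(np.flatnonzero(mask))


__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "SpectraParseError",
    "NonMonotonicWavelengthError",
    "DuplicateSampleIdError",
    "RaggedRowError",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "trim_range",
]
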