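"""Spectral pretreatment: per-spectrum baseline-offset correction and
Savitzky-Golay smoothing.

Both operators leave the wavelength grid untouched.  The study this
package supports found no-pretreatment competitive with either operator,
so the pipeline default is ``none``; the operators are provided for the
comparison.
"""

from __future__ import annotations

from scipy.signal import savgol_filter

from .io import SpectraSet


def baseline_offset(spectra: SpectraSet) -> SpectraSet:
    """Subtract each spectrum's own minimum (baseline-offset correction).

    Every output spectrum has minimum exactly 0; the operator is
    idempotent.
    """
    if spectra.n_samples == 0 or spectra.n_wavelengths == 0:
        raise ValueError("cannot baseline-correct an empty spectra set")
    r = spectra.reflectance
    return SpectraSet(
        spectra.sample_ids, spectra.wavelengths, r - r.min(axis=1, keepdims=True)
    )


def savitzky_golay(spectra: SpectraSet, window: int = 9, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay least-squares smoothing (derivative order 0).

    ``window`` must be odd, larger than ``polyorder`` and no larger than
    the number of channels.  Edges are handled by fitting a polynomial to
    the edge window and evaluating it there.  With
    ``polyorder = window - 1`` the filter is the identity.
    """
    window = int(window)
    polyorder = int(polyorder)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder < 0 or polyorder >= window:
        raise ValueError("polyorder must satisfy 0 <= polyorder < window")
    if window > spectra.n_wavelengths:
        raise ValueError(
            f"window ({window}) exceeds the number of channels "
            f"({spectra.n_wavelengths})"
        )
    smoothed = savgol_filter(
        spectra.reflectance, window_length=window, polyorder=polyorder,
        deriv=0, axis=1, mode="interp",
    )
    return SpectraSet(spectra.sample_ids, spectra.wavelengths, smoothed)


def apply(spectra: SpectraSet, method: str = "none", window: int = 9,
          polyorder: int = 2) -> SpectraSet:
    """Dispatch on a method name: ``none``, ``baseline`` or ``sg``."""
    if method == "none":
        return spectra
    if method == "baseline":
        return baseline_offset(spectra)
    if method == "sg":
        return savitzky_golay(spectra, window=window, polyorder=polyorder)
    raise ValueError(f"unknown preprocessing method {method!r}")


__all__ = ["baseline_offset", "savitzky_golay", "apply"]
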