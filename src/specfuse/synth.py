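"""Two-condition synthetic VIS/NIR reflectance generator.

Emulates a fruit soluble-solids study in which the same product is grown
under two cultivation conditions.  A clean spectrum is a gently sloping
linear baseline minus Gaussian absorption bands whose depths increase with
the sample's soluble-solids content (SSC, %):

    r(lam) = b0 + b1*(lam - start)/(end - start)
             - sum_k (depth_k + slope_k * SSC) * exp(-(lam - c_k - d)^2 / (2 w_k^2))
             + eps,    eps ~ N(0, noise_sd^2)

The second condition differs by a constant baseline offset and a common
band-center shift ``d`` (both zero for the first condition), and by its own
SSC distribution (truncated normal, drawn by rejection).  Default band
centers sit near the water/sugar O-H and C-H features at 970, 1190, 1450
and 1940 nm; the default grid is 350-2500 nm at 1 nm.

Everything is reproducible from ``config.seed``; the two conditions use
independent substreams so adding samples to one never perturbs the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReferenceTable, SpectraSet


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band."""

    center: float  # nm
    width: float  # nm (Gaussian sigma)
    depth: float  # base band depth, reflectance units
    ssc_slope: float  # added depth per % SSC


@dataclass(frozen=True)
class ConditionSpec:
    """SSC distribution of one cultivation condition (truncated normal)."""

    name: str
    ssc_mean: float
    ssc_sd: float
    ssc_min: float
    ssc_max: float


# Defaults mirror the reported SSC statistics of the two cultivation modes
# of the motivating study (open field vs rain shelter).
DEFAULT_CONDITIONS = (
    ConditionSpec("open_field", 26.59, 2.78, 21.2, 35.5),
    ConditionSpec("rain_shelter", 28.81, 3.10, 21.8, 37.4),
)

DEFAULT_BANDS = (
    Band(970.0, 40.0, 0.12, 0.004),
    Band(1190.0, 45.0, 0.08, 0.003),
    Band(1450.0, 60.0, 0.20, 0.005),
    Band(1940.0, 70.0, 0.25, 0.003),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 150
    grid_start: float = 350.0
    grid_end: float = 2500.0
    grid_step: float = 1.0
    baseline_intercept: float = 0.75
    baseline_slope: float = -0.05
    bands: tuple = DEFAULT_BANDS
    conditions: tuple = DEFAULT_CONDITIONS
    baseline_offset: float = 0.05  # applied to the second condition only
    band_center_shift: float = 15.0  # nm, second condition only
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.grid_start >= self.grid_end:
            raise ValueError("grid_start must be below grid_end")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for band in self.bands:
            if band.width <= 0:
                raise ValueError(f"band at {band.center} nm has non-positive width")
        names = [c.name for c in self.conditions]
        if len(self.conditions) != 2 or len(set(names)) != 2:
            raise ValueError("exactly two distinctly named conditions are required")
        for c in self.conditions:
            if not c.ssc_min < c.ssc_max:
                raise ValueError(f"condition {c.name}: ssc_min must be below ssc_max")
            if c.ssc_sd <= 0:
                raise ValueError(f"condition {c.name}: ssc_sd must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    def condition_index(self, name: str) -> int:
        for i, c in enumerate(self.conditions):
            if c.name == name:
                return i
        raise ValueError(
            f"unknown condition {name!r}; expected one of "
            f"{[c.name for c in self.conditions]}"
        )


def _clean_spectrum(config: SyntheticConfig, ssc, shift_nm: float, offset: float):
    """Noise-free reflectance matrix for SSC values (vectorized over samples)."""
    lam = config.wavelengths
    frac = (lam - config.grid_start) / (config.grid_end - config.grid_start)
    base = config.baseline_intercept + config.baseline_slope * frac + offset
    ssc = np.atleast_1d(np.asarray(ssc, dtype=float))
    r = np.tile(base, (ssc.size, 1))
    for band in config.bands:
        profile = np.exp(-((lam - band.center - shift_nm) ** 2) / (2 * band.width**2))
        depth = band.depth + band.ssc_slope * ssc
        r -= depth[:, None] * profile[None, :]
    return r


def _validate_depths(config: SyntheticConfig, index: int) -> None:
    cond = config.conditions[index]
    shift = config.band_center_shift if index == 1 else 0.0
    offset = config.baseline_offset if index == 1 else 0.0
    worst = _clean_spectrum(config, cond.ssc_max, shift, offset)
    if worst.min() <= 0:
        raise ValueError(
            f"condition {cond.name}: band depths exceed the baseline at "
            f"SSC={cond.ssc_max}% (reflectance would go non-positive)"
        )


def _truncated_normal(rng, mean, sd, lo, hi, n):
    """Rejection sampling from N(mean, sd^2) truncated to [lo, hi]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_condition(
    config: SyntheticConfig, condition: str, ssc=None
) -> tuple[SpectraSet, ReferenceTable]:
    """Generate one condition's spectra and reference SSC values.

    Parameters
    ----------
    condition
        Name of one of the two configured conditions.  The second
        condition receives the baseline offset and band-center shift.
    ssc
        Optional explicit SSC values (%, one per sample); drawn from the
        condition's truncated normal when omitted.
    """
    index = config.condition_index(condition)
    _validate_depths(config, index)
    cond = config.conditions[index]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(index,))
    )
    if ssc is None:
        ssc = _truncated_normal(
            rng, cond.ssc_mean, cond.ssc_sd, cond.ssc_min, cond.ssc_max, config.n_samples
        )
    else:
        ssc = np.asarray(ssc, dtype=float)
    shift = config.band_center_shift if index == 1 else 0.0
    offset = config.baseline_offset if index == 1 else 0.0
    clean = _clean_spectrum(config, ssc, shift, offset)
    noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
    ids = tuple(f"{cond.name}-{i:03d}" for i in range(len(ssc)))
    spectra = SpectraSet(ids, config.wavelengths, clean + noise)
    return spectra, ReferenceTable(ids, ssc)


def generate_study(config: SyntheticConfig) -> dict:
    """Generate both conditions; returns {name: (SpectraSet, ReferenceTable)}."""
    return {c.name: generate_condition(config, c.name) for c in config.conditions}


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a flat mapping (YAML-friendly)."""
    d = dict(d)
    if "bands" in d:
        d["bands"] = tuple(Band(*b) if not isinstance(b, Band) else b for b in d["bands"])
    if "conditions" in d:
        d["conditions"] = tuple(
            ConditionSpec(**c) if isinstance(c, dict) else c for c in d["conditions"]
        )
    return SyntheticConfig(**d)


__all__ = [
    "Band",
    "ConditionSpec",
    "SyntheticConfig",
    "DEFAULT_BANDS",
    "DEFAULT_CONDITIONS",
    "generate_condition",
    "generate_study",
    "config_from_dict",
]
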