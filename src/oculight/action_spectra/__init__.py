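"""Reference spectral weighting functions and the age correction.

Exposes the five alpha-opic photoreceptor sensitivities (S-, M-, L-cone-opic,
rhodopic, melanopic), the photopic luminous efficiency function V(lambda) and
the retinal blue-light hazard function B(lambda), loaded from vendored ASCII
tables with verified checksums, plus the age-dependent pre-receptoral
filtering correction relative to the 32-year standard observer.

The vendored tables are synthetic stand-ins for the official standardized
tabulations; see :mod:`oculight.action_spectra._synthesis` for how they are
constructed and :mod:`oculight.action_spectra.lens` for the lens aging model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from ..spectral_core import WavelengthGrid, read_spd, Kind
from . import lens
from ._synthesis import ALL_NAMES, ALPHA_OPIC_NAMES, DATA_DIR
from .lens import AGE_VALIDITY_RANGE, STANDARD_OBSERVER_AGE

__all__ = [
    "ActionSpectrum",
    "LensCorrection",
    "ALPHA_OPIC_NAMES",
    "ALL_NAMES",
    "STANDARD_OBSERVER_AGE",
    "AGE_VALIDITY_RANGE",
    "load_reference_functions",
    "get_function",
    "peak_wavelength",
    "lens_correction",
    "lens_corrected_weighting",
]

_UNIT_PEAK_TOL = 1e-6


@dataclass(frozen=True)
class ActionSpectrum:
    """A named, dimensionless spectral weighting function.

    All alpha-opic functions and V(lambda) are unit-peak normalized
    (max weight = 1 within 1e-6); weights are non-negative everywhere.
    """

    name: str
    grid: WavelengthGrid
    weights: np.ndarray
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != self.grid.values.shape:
            raise ValueError("weights length does not match grid length")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError(f"action spectrum {self.name!r}: weights must be finite and >= 0")


@dataclass(frozen=True)
class LensCorrection:
    """Per-wavelength multiplicative correction relative to the 32-year observer."""

    age: float
    grid: WavelengthGrid
    spectral_factor: np.ndarray


def _load_one(name: str, checksums: Mapping[str, str]) -> ActionSpectrum:
    fname = f"synthetic_{name}.csv"
    path = DATA_DIR / fname
    if not path.exists():
        raise RuntimeError(f"vendored table for {name!r} missing: {path}")
    text = path.read_text(encoding="ascii")
    digest = hashlib.sha256(text.encode("ascii")).hexdigest()
    if checksums.get(fname) != digest:
        raise RuntimeError(
            f"vendored table for {name!r} corrupt: sha256 {digest} does not match manifest"
        )
    # the tables share the SPD file dialect; weights are dimensionless, so the
    # kind argument is irrelevant and its units warning is suppressed
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spd = read_spd(str(path), Kind.IRRADIANCE)
    a = ActionSpectrum(name=name, grid=spd.grid, weights=spd.values, metadata=spd.metadata)
    if name != "blue_light_hazard":
        peak = float(np.max(a.weights))
        if abs(peak - 1.0) > _UNIT_PEAK_TOL:
            raise RuntimeError(f"table for {name!r} not unit-peak normalized (max {peak})")
    return a


@lru_cache(maxsize=1)
def load_reference_functions() -> dict[str, ActionSpectrum]:
    """Load and checksum-verify all seven vendored weighting functions."""
    manifest_path = DATA_DIR / "checksums.json"
    if not manifest_path.exists():
        raise RuntimeError(f"checksum manifest missing: {manifest_path}")
    checksums = json.loads(manifest_path.read_text(encoding="ascii"))
    return {name: _load_one(name, checksums) for name in ALL_NAMES}


def get_function(name: str) -> ActionSpectrum:
    funcs = load_reference_functions()
    if name not in funcs:
        raise KeyError(f"unknown weighting function {name!r}; known: {sorted(funcs)}")
    return funcs[name]


def peak_wavelength(a: ActionSpectrum) -> float:
    """Wavelength (nm) of the maximum weight; ties break toward the lowest wavelength.

    Note this is the peak of the corneally referenced tabulated function,
    which sits longward of the underlying pigment peak because pre-receptoral
    filtering attenuates short wavelengths.
    """
    if not np.any(a.weights > 0):
        raise ValueError(f"action spectrum {a.name!r} is all-zero; peak undefined")
    return float(a.grid.values[int(np.argmax(a.weights))])


def lens_correction(age: float, grid: WavelengthGrid | None = None) -> LensCorrection:
    """Spectral correction factor for an observer of ``age`` years.

    Factor = lens transmittance at ``age`` / transmittance at the 32-year
    standard; identically 1 at age 32.  Ages outside the model validity range
    raise (no clamping — silent lens-density extrapolation is unsafe).
    """
    if grid is None:
        grid = WavelengthGrid.uniform(380.0, 780.0, 1.0)
    factor = lens.relative_transmittance_factor(grid.values, age)
    return LensCorrection(age=float(age), grid=grid, spectral_factor=factor)


def lens_corrected_weighting(a: ActionSpectrum, age: float) -> ActionSpectrum:
    """Weighting function for an observer of ``age`` years.

    Multiplies the standard-observer weights by the relative lens
    transmittance; at age 32 this returns the input unchanged.  The result is
    deliberately not re-normalized: the reduced short-wavelength throughput is
    the physical effect being modelled.
    """
    corr = lens_correction(age, a.grid)
    if corr.age == STANDARD_OBSERVER_AGE:
        return a
    return replace(
        a,
        weights=a.weights * corr.spectral_factor,
        metadata={**dict(a.metadata), "observer_age_years": f"{float(age):g}"},
    )
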