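"""Reportable scalars derived from an SPD.

Implements the retinally referenced quantities that should accompany any
tabulated spectrum: the alpha-opic panel (one weighted integral per
photoreceptor class, in mW/m² for irradiance input or mW/(m²·sr) for radiance
input), the photopic illuminance (lux) or luminance (cd/m²), photon
irradiance (photons·cm⁻²·s⁻¹ and its log10), and the observer-age
sensitivity analysis in which the panel is recomputed for a set of candidate
observer ages.

Conventions: weighted integrals are rectangle sums on a common 1-nm grid
(Δλ × Σ product), matching tabulated-toolbox practice; the luminous efficacy
constant is exactly 683 lm/W; h and c are the CODATA 2018 exact values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import action_spectra
from .action_spectra import (
    ALPHA_OPIC_NAMES,
    STANDARD_OBSERVER_AGE,
    ActionSpectrum,
    get_function,
    lens_corrected_weighting,
)
from .spectral_core import Kind, SpectralMeasurement, WavelengthGrid, resample

__all__ = [
    "LUMINOUS_EFFICACY_LM_PER_W",
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "AlphaOpicPanel",
    "PhotonReport",
    "weighted_integral",
    "alpha_opic_panel",
    "photon_report",
    "age_sensitivity_analysis",
    "panel_to_dict",
    "panels_to_frame",
]

#: Maximum luminous efficacy K_m, lm/W (683 exactly by convention here).
LUMINOUS_EFFICACY_LM_PER_W = 683.0
#: Planck constant, J·s (exact).
PLANCK_H = 6.62607015e-34
#: Speed of light in vacuum, m/s (exact).
SPEED_OF_LIGHT = 299_792_458.0


@dataclass(frozen=True)
class AlphaOpicPanel:
    """The five alpha-opic values plus the photopic quantity for one SPD.

    Alpha-opic entries are in mW/m² (irradiance input) or mW/(m²·sr)
    (radiance input); ``photopic`` is illuminance in lux for irradiance input
    and luminance in cd/m² for radiance input.
    """

    s_cone_opic: float
    m_cone_opic: float
    l_cone_opic: float
    rhodopic: float
    melanopic: float
    photopic: float
    input_kind: Kind
    observer_age: float = STANDARD_OBSERVER_AGE

    @property
    def alpha_opic_unit(self) -> str:
        return "mW/m^2" if self.input_kind is Kind.IRRADIANCE else "mW/(m^2 sr)"

    @property
    def photopic_unit(self) -> str:
        return "lux" if self.input_kind is Kind.IRRADIANCE else "cd/m^2"

    def alpha_opic_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ALPHA_OPIC_NAMES}


@dataclass(frozen=True)
class PhotonReport:
    """Photon irradiance summary: total rate, its log10, and the per-wavelength spectrum."""

    total_photon_irradiance: float  # photons·cm⁻²·s⁻¹
    log10_total: float | None  # None when the total is zero
    grid: WavelengthGrid
    per_wavelength: np.ndarray  # photons·cm⁻²·s⁻¹·nm⁻¹


def _common_grid(spd: SpectralMeasurement, a: ActionSpectrum) -> WavelengthGrid:
    lo = max(spd.grid.support[0], a.grid.support[0])
    hi = min(spd.grid.support[1], a.grid.support[1])
    if hi < lo:
        raise ValueError(
            f"SPD support {spd.grid.support} nm and weighting function "
            f"{a.name!r} support {a.grid.support} nm do not overlap"
        )
    lo_i, hi_i = np.ceil(lo), np.floor(hi)
    return WavelengthGrid.uniform(float(lo_i), float(hi_i), 1.0)


def weighted_integral(spd: SpectralMeasurement, a: ActionSpectrum) -> float:
    """Σ spd(λ)·a(λ)·Δλ on a common 1-nm grid over the overlapping support.

    Returns the weighted quantity in the SPD's own energy units (W/m² or
    W/(m²·sr)); unit conversions happen at panel assembly.
    """
    common = _common_grid(spd, a)
    s = resample(spd, common, _warn_outside=False).values
    w = np.interp(common.values, a.grid.values, a.weights, left=0.0, right=0.0)
    step = common.step if common.step is not None else 1.0
    return float(np.sum(s * w) * step)


def _corrected(name: str, age: float) -> ActionSpectrum:
    a = get_function(name)
    if age == STANDARD_OBSERVER_AGE:
        return a
    return lens_corrected_weighting(a, age)


def alpha_opic_panel(spd: SpectralMeasurement, age: float = STANDARD_OBSERVER_AGE) -> AlphaOpicPanel:
    """Compute the five alpha-opic values (mW) and the photopic quantity.

    For non-standard ages the alpha-opic weighting functions are corrected
    for lens aging; the photopic entry always uses the standard V(lambda),
    since photometric units are defined for the standard observer.
    """
    values = {
        name: 1000.0 * weighted_integral(spd, _corrected(name, age))
        for name in ALPHA_OPIC_NAMES
    }
    photopic = LUMINOUS_EFFICACY_LM_PER_W * weighted_integral(spd, get_function("photopic_V"))
    return AlphaOpicPanel(
        **values, photopic=photopic, input_kind=spd.kind, observer_age=float(age)
    )


def photon_report(spd: SpectralMeasurement) -> PhotonReport:
    """Convert a spectral irradiance to photon irradiance.

    Per-wavelength photon rate is E(λ)·λ/(h·c), with λ in metres, scaled by
    1e-4 from m⁻² to cm⁻².  Radiance input is rejected (photon radiance is
    not a reporting quantity here).
    """
    if spd.kind is not Kind.IRRADIANCE:
        raise ValueError("photon irradiance requires a spectral-irradiance SPD")
    lam_m = spd.grid.values * 1e-9
    per_wl = spd.values * lam_m / (PLANCK_H * SPEED_OF_LIGHT) * 1e-4
    if spd.grid.step is not None:
        total = float(np.sum(per_wl) * spd.grid.step)
    else:
        total = float(np.trapezoid(per_wl, spd.grid.values))
    log10_total = float(np.log10(total)) if total > 0 else None
    return PhotonReport(
        total_photon_irradiance=total,
        log10_total=log10_total,
        grid=spd.grid,
        per_wavelength=per_wl,
    )


def age_sensitivity_analysis(
    spd: SpectralMeasurement, ages: Iterable[float]
) -> pd.DataFrame:
    """Alpha-opic panel for a set of candidate observer ages, one row per age.

    The row at age 32 is identical to the uncorrected panel.  Useful whenever
    stimuli rely on assumed lens properties (e.g., metameric lights).
    """
    ages = [float(x) for x in ages]
    if not ages:
        raise ValueError("age list must not be empty")
    rows = [panel_to_dict(alpha_opic_panel(spd, age)) for age in ages]
    frame = pd.DataFrame(rows, index=pd.Index(ages, name="age_years"))
    return frame.drop(columns=["observer_age_years"])


# ---------------------------------------------------------------------------
# Export helpers


def panel_to_dict(panel: AlphaOpicPanel) -> dict[str, float | str]:
    """Flatten a panel with units embedded in the key names."""
    unit = panel.alpha_opic_unit.replace("/", "_per_").replace("^", "").replace(" ", "")
    out: dict[str, float | str] = {
        f"{name}_{unit}": getattr(panel, name) for name in ALPHA_OPIC_NAMES
    }
    if panel.input_kind is Kind.IRRADIANCE:
        out["photopic_illuminance_lux"] = panel.photopic
    else:
        out["photopic_luminance_cd_per_m2"] = panel.photopic
    out["observer_age_years"] = panel.observer_age
    out["input_kind"] = panel.input_kind.value
    return out


def panels_to_frame(panels: Mapping[str, AlphaOpicPanel]) -> pd.DataFrame:
    """Tabulate several labelled panels (e.g., stimulus and background)."""
    return pd.DataFrame({k: panel_to_dict(v) for k, v in panels.items()}).T
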