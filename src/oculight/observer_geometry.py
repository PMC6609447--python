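"""Observer-side optics: visual angle, light-adapted pupil size, trolands.

The biologically effective quantity is retinal intensity, which depends on
the stimulus geometry (angular subtense), the pupil, and the luminance.  This
module computes the visual angle θ = 2·atan(0.5·S/d), predicts the
light-adapted pupil diameter with the Watson & Yellott (2012) unified
formula (field size, luminance, age, one vs two eyes), and converts
luminance to retinal illuminance in trolands (luminance × pupil area in mm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .quantities import alpha_opic_panel
from .spectral_core import Kind, SpectralMeasurement

__all__ = [
    "PUPIL_MODEL_ID",
    "StimulusGeometry",
    "ObserverContext",
    "RetinalIlluminance",
    "visual_angle",
    "predicted_pupil_diameter",
    "trolands",
    "retinal_illuminance",
]

#: Identifier of the pupil-model variant, recorded in outputs for traceability.
PUPIL_MODEL_ID = "watson_yellott_2012_unified"

_PUPIL_BOUNDS_MM = (1.0, 10.0)
# Watson & Yellott (2012) unified-formula constants
_REFERENCE_AGE_Y = 28.58
_MONOCULAR_FLUX_FACTOR = 0.1


@dataclass(frozen=True)
class StimulusGeometry:
    """Physical extent and viewing distance of the stimulus."""

    width_m: float
    height_m: float
    distance_m: float
    shape: str = ""

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValueError("viewing distance must be > 0 m")
        if self.width_m < 0 or self.height_m < 0:
            raise ValueError("object sizes must be >= 0 m")

    @property
    def visual_angle_deg(self) -> tuple[float, float]:
        """(horizontal, vertical) angular subtense in degrees."""
        return (
            visual_angle(self.width_m, self.distance_m),
            visual_angle(self.height_m, self.distance_m),
        )


@dataclass(frozen=True)
class ObserverContext:
    """Observer-side parameters needed for pupil and troland computations."""

    age: float = 32.0
    eyes_open: int = 2
    field_diameter_deg: float = 10.0
    pupil_diameter_mm: Optional[float] = None  # measured/artificial pupil, if any
    dilation_agent: str = ""  # pharmacological agent, free text

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be > 0 years")
        if self.eyes_open not in (1, 2):
            raise ValueError("eyes_open must be 1 or 2")
        if self.field_diameter_deg <= 0:
            raise ValueError("field diameter must be > 0 degrees")
        if self.pupil_diameter_mm is not None and self.pupil_diameter_mm <= 0:
            raise ValueError("measured pupil diameter must be > 0 mm")


@dataclass(frozen=True)
class RetinalIlluminance:
    """Retinal illuminance plus the provenance of the pupil diameter used."""

    trolands: float
    luminance_cd_m2: float
    pupil_diameter_mm: float
    pupil_source: str  # "measured" or "modelled"
    pupil_model: Optional[str] = None  # set when pupil_source == "modelled"


def visual_angle(size_m: float, distance_m: float) -> float:
    """Angular subtense θ = 2·atan(0.5·S/d), in degrees, per dimension."""
    if distance_m <= 0:
        raise ValueError("distance must be > 0 m")
    if size_m < 0:
        raise ValueError("size must be >= 0 m")
    return math.degrees(2.0 * math.atan(0.5 * size_m / distance_m))


def _stanley_davies(flux: float) -> float:
    # base light-adapted diameter as a function of corneal flux density (cd·deg²/m²)
    t = (flux / 846.0) ** 0.41
    return 7.75 - 5.75 * t / (t + 2.0)


def predicted_pupil_diameter(luminance_cd_m2: float, ctx: ObserverContext) -> float:
    """Light-adapted pupil diameter (mm), Watson & Yellott unified formula.

    Effective corneal flux density F = L·a·M(e), with a the field area in
    deg² and M(e) = 1 for binocular, 0.1 for monocular viewing; the
    Stanley–Davies diameter at F is then age-adjusted around the reference
    age 28.58 y.  The result is clamped to the physiological 1–10 mm range.
    The model ignores non-luminance contributions to pupil control.
    """
    if luminance_cd_m2 < 0:
        raise ValueError("luminance must be >= 0 cd/m^2")
    area_deg2 = math.pi * (ctx.field_diameter_deg / 2.0) ** 2
    eye_factor = 1.0 if ctx.eyes_open == 2 else _MONOCULAR_FLUX_FACTOR
    flux = luminance_cd_m2 * area_deg2 * eye_factor
    d_sd = _stanley_davies(flux)
    d = d_sd + (ctx.age - _REFERENCE_AGE_Y) * (0.02132 - 0.009562 * d_sd)
    return min(max(d, _PUPIL_BOUNDS_MM[0]), _PUPIL_BOUNDS_MM[1])


def trolands(luminance_cd_m2: float, pupil_diameter_mm: float) -> float:
    """Retinal illuminance: luminance × pupil area (mm²), in trolands."""
    if luminance_cd_m2 < 0 or pupil_diameter_mm < 0:
        raise ValueError("luminance and pupil diameter must be >= 0")
    area_mm2 = math.pi * (pupil_diameter_mm / 2.0) ** 2
    return luminance_cd_m2 * area_mm2


def retinal_illuminance(
    spd_radiance: SpectralMeasurement, ctx: ObserverContext
) -> RetinalIlluminance:
    """Trolands from a spectral radiance and an observer context.

    The luminance comes from the photopic entry of the alpha-opic panel; the
    pupil diameter is the measured value when the context provides one
    (tagged "measured"), otherwise the model prediction (tagged "modelled").
    """
    if spd_radiance.kind is not Kind.RADIANCE:
        raise ValueError("retinal illuminance requires a spectral-radiance SPD")
    luminance = alpha_opic_panel(spd_radiance).photopic
    if ctx.pupil_diameter_mm is not None:
        pupil, source, model = ctx.pupil_diameter_mm, "measured", None
    else:
        pupil = predicted_pupil_diameter(luminance, ctx)
        source, model = "modelled", PUPIL_MODEL_ID
    return RetinalIlluminance(
        trolands=trolands(luminance, pupil),
        luminance_cd_m2=luminance,
        pupil_diameter_mm=pupil,
        pupil_source=source,
        pupil_model=model,
    )
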