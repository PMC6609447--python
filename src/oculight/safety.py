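"""Photobiological safety pre-screen (retinal blue-light hazard).

Implements the screening logic for the photochemical retinal hazard: sources
with luminance below 10,000 cd/m² are exempt from detailed measurement; for
brighter sources viewed longer than 10,000 s, the blue-light-weighted
radiance is compared against the risk-group-0 limit of 100 W/(m²·sr).

This is a pre-screen, not a certification: compliance with light-safety
regulations needs to be checked and confirmed on a case-by-case basis, and
the full risk-group ladder (RG1–RG3), thermal, UV and skin hazards are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .action_spectra import get_function
from .quantities import alpha_opic_panel, weighted_integral
from .spectral_core import Kind, SpectralMeasurement

__all__ = [
    "RG0_RADIANCE_LIMIT_W_M2_SR",
    "LUMINANCE_EXEMPTION_CD_M2",
    "LONG_EXPOSURE_THRESHOLD_S",
    "SAFETY_CAVEAT",
    "Verdict",
    "SafetyScreenResult",
    "blue_light_weighted_radiance",
    "rg0_screen",
]

#: Risk-group-0 limit for blue-light-weighted radiance at exposures > 10,000 s.
RG0_RADIANCE_LIMIT_W_M2_SR = 100.0
#: Below this luminance, detailed safety measurements are typically not required.
LUMINANCE_EXEMPTION_CD_M2 = 10_000.0
#: Exposure duration above which the long-exposure RG0 radiance limit applies.
LONG_EXPOSURE_THRESHOLD_S = 10_000.0

SAFETY_CAVEAT = (
    "Compliance with light safety regulations needs to be checked and "
    "confirmed on a case-by-case basis."
)

#: Hazard-function tabulation used, recorded for traceability.
HAZARD_FUNCTION_EDITION = "synthetic stand-in, piecewise B(lambda), 5 nm, 300-700 nm"


class Verdict(str, Enum):
    EXEMPT_LOW_LUMINANCE = "exempt_low_luminance"
    RG0_PASS = "rg0_pass"
    RG0_EXCEEDED = "rg0_exceeded"


@dataclass(frozen=True)
class SafetyScreenResult:
    verdict: Verdict
    luminance_cd_m2: float
    exposure_duration_s: float
    weighted_radiance_w_m2_sr: Optional[float]  # None when the radiance test did not run
    rationale: str
    hazard_function_edition: str = HAZARD_FUNCTION_EDITION


def blue_light_weighted_radiance(spd: SpectralMeasurement) -> float:
    """Radiance weighted by the blue-light hazard function B(λ), W/(m²·sr)."""
    if spd.kind is not Kind.RADIANCE:
        raise ValueError("blue-light-weighted radiance requires a spectral-radiance SPD")
    return weighted_integral(spd, get_function("blue_light_hazard"))


def rg0_screen(spd: SpectralMeasurement, exposure_duration_s: float) -> SafetyScreenResult:
    """Screen a radiance SPD against the risk-group-0 blue-light limit.

    Decision order: luminance below the 10,000 cd/m² exemption short-circuits
    the radiance test; otherwise the weighted radiance is compared against the
    100 W/(m²·sr) RG0 limit, which is binding only for exposures longer than
    10,000 s — shorter high-luminance exposures above the limit return a pass
    with a rationale noting the long-exposure limit was not triggered.
    """
    if spd.kind is not Kind.RADIANCE:
        raise ValueError("the safety screen requires a spectral-radiance SPD")
    if exposure_duration_s <= 0:
        raise ValueError("exposure duration must be > 0 s")

    luminance = alpha_opic_panel(spd).photopic
    if luminance < LUMINANCE_EXEMPTION_CD_M2:
        return SafetyScreenResult(
            verdict=Verdict.EXEMPT_LOW_LUMINANCE,
            luminance_cd_m2=luminance,
            exposure_duration_s=float(exposure_duration_s),
            weighted_radiance_w_m2_sr=None,
            rationale=(
                f"Luminance {luminance:.1f} cd/m^2 is below "
                f"{LUMINANCE_EXEMPTION_CD_M2:.0f} cd/m^2; detailed safety "
                f"measurements are typically not required. {SAFETY_CAVEAT}"
            ),
        )

    weighted = blue_light_weighted_radiance(spd)
    if weighted > RG0_RADIANCE_LIMIT_W_M2_SR and exposure_duration_s > LONG_EXPOSURE_THRESHOLD_S:
        verdict = Verdict.RG0_EXCEEDED
        rationale = (
            f"Blue-light-weighted radiance {weighted:.2f} W/(m^2 sr) exceeds the "
            f"risk-group-0 limit of {RG0_RADIANCE_LIMIT_W_M2_SR:.0f} W/(m^2 sr) at an "
            f"exposure of more than {LONG_EXPOSURE_THRESHOLD_S:.0f} s. {SAFETY_CAVEAT}"
        )
    elif weighted > RG0_RADIANCE_LIMIT_W_M2_SR:
        verdict = Verdict.RG0_PASS
        rationale = (
            f"Blue-light-weighted radiance {weighted:.2f} W/(m^2 sr) is above the "
            f"long-exposure risk-group-0 limit, but the exposure duration "
            f"{exposure_duration_s:.0f} s does not exceed "
            f"{LONG_EXPOSURE_THRESHOLD_S:.0f} s, so the long-exposure limit was not "
            f"triggered; time-dependent limits are not evaluated by this pre-screen. "
            f"{SAFETY_CAVEAT}"
        )
    else:
        verdict = Verdict.RG0_PASS
        rationale = (
            f"Blue-light-weighted radiance {weighted:.2f} W/(m^2 sr) is within the "
            f"risk-group-0 limit of {RG0_RADIANCE_LIMIT_W_M2_SR:.0f} W/(m^2 sr). "
            f"{SAFETY_CAVEAT}"
        )
    return SafetyScreenResult(
        verdict=verdict,
        luminance_cd_m2=luminance,
        exposure_duration_s=float(exposure_duration_s),
        weighted_radiance_w_m2_sr=weighted,
        rationale=rationale,
    )
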