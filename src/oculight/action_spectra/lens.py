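"""Age-dependent crystalline-lens density model (synthetic stand-in).

Pre-receptoral filtering by the ocular media attenuates short wavelengths,
and the attenuation grows with age as the lens yellows.  The standardized
weighting functions are defined for a 32-year-old standard observer; light
exposure for other observers is modelled by rescaling the weighting function
with the ratio of lens transmittances at the target age and at 32 years.

This module implements the classic two-component lens-density aging model
(a wavelength-dependent aging component ``TL1`` scaled linearly with age,
plus a stable component ``TL2``; Pokorny, Smith & Lutze 1987 lineage).  It is
a synthetic stand-in for the official standardized lens formula, which is not
redistributable here; it reproduces the standard's qualitative structure:
identity at age 32, monotone short-wavelength attenuation with age, no
effect at long wavelengths.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STANDARD_OBSERVER_AGE",
    "AGE_VALIDITY_RANGE",
    "lens_density",
    "lens_transmittance",
    "relative_transmittance_factor",
]

STANDARD_OBSERVER_AGE = 32.0
#: Ages (years) for which the two-component model is defined.
AGE_VALIDITY_RANGE = (20.0, 80.0)

# 10-nm tabulation of the two density components, 380-780 nm.  Values for
# 400-650 nm follow the published two-component tabulation; 380-395 nm are a
# smooth short-wavelength continuation (synthetic); both components are zero
# above 650 nm.
_WL = np.arange(380.0, 781.0, 10.0)

_TL1 = np.array(
    [
        0.780, 0.690,  # 380, 390 (continuation)
        0.600, 0.510, 0.433, 0.377, 0.327, 0.295, 0.267, 0.233, 0.207, 0.187,  # 400-490
        0.167, 0.147, 0.133, 0.120, 0.107, 0.093, 0.080, 0.067, 0.053, 0.040,  # 500-590
        0.033, 0.027, 0.020, 0.013, 0.007, 0.000,  # 600-650
    ]
    + [0.0] * 13  # 660-780
)

_TL2 = np.array(
    [
        3.000, 1.900,  # 380, 390 (continuation; lens blocks near-UV steeply)
        1.000, 0.583, 0.300, 0.116, 0.033, 0.005, 0.000,  # 400-460
    ]
    + [0.0] * 32  # 470-780
)

assert _TL1.size == _WL.size and _TL2.size == _WL.size


def _check_age(age: float) -> float:
    age = float(age)
    lo, hi = AGE_VALIDITY_RANGE
    if not (lo <= age <= hi):
        raise ValueError(
            f"observer age {age} years outside the lens model validity range "
            f"{lo:g}–{hi:g} years (no extrapolation)"
        )
    return age


def _aging_gain(age: float) -> float:
    # multiplier applied to TL1 relative to its value at age 32
    if age <= 60.0:
        return 1.0 + 0.02 * (age - STANDARD_OBSERVER_AGE)
    return 1.56 + 0.0667 * (age - 60.0)


def lens_density(wavelengths_nm: np.ndarray, age: float) -> np.ndarray:
    """Lens optical density (decadic) at ``age`` years, linearly interpolated."""
    age = _check_age(age)
    wl = np.asarray(wavelengths_nm, dtype=float)
    tl1 = np.interp(wl, _WL, _TL1, left=_TL1[0], right=0.0)
    tl2 = np.interp(wl, _WL, _TL2, left=_TL2[0], right=0.0)
    return tl1 * _aging_gain(age) + tl2


def lens_transmittance(wavelengths_nm: np.ndarray, age: float) -> np.ndarray:
    """Spectral transmittance 10^(-density)."""
    return 10.0 ** (-lens_density(wavelengths_nm, age))


def relative_transmittance_factor(wavelengths_nm: np.ndarray, age: float) -> np.ndarray:
    """Transmittance at ``age`` divided by transmittance at the 32-year standard.

    Exactly 1 at every wavelength for age 32; <= 1 at short wavelengths for
    older observers (lens yellowing), monotone non-increasing with age.
    """
    age = _check_age(age)
    wl = np.asarray(wavelengths_nm, dtype=float)
    tl1 = np.interp(wl, _WL, _TL1, left=_TL1[0], right=0.0)
    delta = tl1 * (_aging_gain(age) - 1.0)
    return 10.0 ** (-delta)
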