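"""Construction of the vendored synthetic weighting-function tables.

The package needs seven spectral weighting functions: the five photoreceptor
(alpha-opic) sensitivities (S-, M-, L-cone-opic, rhodopic, melanopic), the
photopic luminous efficiency function V(lambda), and the retinal blue-light
photochemical-hazard function B(lambda).  The official standardized electronic
tabulations are not redistributable here, so the vendored tables are SYNTHETIC
stand-ins constructed from published building blocks:

* alpha-opic functions: the Govardovskii et al. (2000) A1 visual-pigment
  template evaluated at the accepted pigment peaks (S 420 nm, M 530 nm,
  L 558 nm, rods 500 nm, melanopsin 480 nm), filtered through the two-component
  lens-density model at the 32-year standard observer age (plus a macular
  pigment template for the cones, which sit behind macular pigment; rods and
  melanopsin ipRGC sensitivities are treated as extra-macular), then
  unit-peak normalized on the 1-nm 380-780 nm grid.
* photopic V(lambda): the widely published 5-nm photopic luminous efficiency
  tabulation (peak 1.0 at 555 nm), linearly interpolated to 1 nm.
* blue-light hazard B(lambda): the widely published piecewise hazard
  tabulation (unit peak across 435-440 nm, 10**((450-λ)/50) roll-off from
  500-600 nm, 1e-3 plateau to 700 nm) on its native 5-nm 300-700 nm grid.

Running this module as a script regenerates the ASCII tables and the checksum
manifest under ``action_spectra/data/``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from ..spectral_core import WavelengthGrid
from .lens import STANDARD_OBSERVER_AGE, lens_transmittance

DATA_DIR = Path(__file__).parent / "data"

ALPHA_OPIC_NAMES = ("s_cone_opic", "m_cone_opic", "l_cone_opic", "rhodopic", "melanopic")
ALL_NAMES = ALPHA_OPIC_NAMES + ("photopic_V", "blue_light_hazard")

#: Visual-pigment peak wavelengths (nm) used for the alpha-opic templates.
PIGMENT_PEAKS_NM = {
    "s_cone_opic": 420.0,
    "m_cone_opic": 530.0,
    "l_cone_opic": 558.0,
    "rhodopic": 500.0,
    "melanopic": 480.0,
}

_MACULAR_PEAK_DENSITY = 0.10  # decadic, 10-degree-field scale
_MACULAR_PEAK_NM = 460.0
_MACULAR_SIGMA_NM = 25.0


def govardovskii_template(wavelengths_nm: np.ndarray, peak_nm: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha band + beta band)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = peak_nm / wl
    a = 0.8795 + 0.0459 * np.exp(-((peak_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    peak_beta = 189.0 + 0.315 * peak_nm
    band_beta = -40.5 + 0.195 * peak_nm
    beta = 0.26 * np.exp(-(((wl - peak_beta) / band_beta) ** 2))
    return alpha + beta


def macular_transmittance(wavelengths_nm: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths_nm, dtype=float)
    density = _MACULAR_PEAK_DENSITY * np.exp(
        -((wl - _MACULAR_PEAK_NM) ** 2) / (2.0 * _MACULAR_SIGMA_NM**2)
    )
    return 10.0 ** (-density)


# Widely published photopic luminous efficiency values, 380-780 nm at 5 nm.
_V_LAMBDA_5NM = np.array([
    0.000039, 0.000064, 0.000120, 0.000217, 0.000396, 0.000640, 0.001210,
    0.002180, 0.004000, 0.007300, 0.011600, 0.016840, 0.023000, 0.029800,
    0.038000, 0.048000, 0.060000, 0.073900, 0.090980, 0.112600, 0.139020,
    0.169300, 0.208020, 0.258600, 0.323000, 0.407300, 0.503000, 0.608200,
    0.710000, 0.793200, 0.862000, 0.914850, 0.954000, 0.980300, 0.994950,
    1.000000, 0.995000, 0.978600, 0.952000, 0.915400, 0.870000, 0.816300,
    0.757000, 0.694900, 0.631000, 0.566800, 0.503000, 0.441200, 0.381000,
    0.321000, 0.265000, 0.217000, 0.175000, 0.138200, 0.107000, 0.081600,
    0.061000, 0.044580, 0.032000, 0.023200, 0.017000, 0.011920, 0.008210,
    0.005723, 0.004102, 0.002929, 0.002091, 0.001484, 0.001047, 0.000740,
    0.000520, 0.000361, 0.000249, 0.000172, 0.000120, 0.0000848, 0.0000600,
    0.0000424, 0.0000300, 0.0000212, 0.0000149,
])
assert _V_LAMBDA_5NM.size == 81


def _blue_light_hazard_table() -> tuple[np.ndarray, np.ndarray]:
    wl = np.arange(300.0, 701.0, 5.0)
    explicit = {
        385: 0.013, 390: 0.025, 395: 0.05, 400: 0.10, 405: 0.20, 410: 0.40,
        415: 0.80, 420: 0.90, 425: 0.95, 430: 0.98, 435: 1.00, 440: 1.00,
        445: 0.97, 450: 0.94, 455: 0.90, 460: 0.80, 465: 0.70, 470: 0.62,
        475: 0.55, 480: 0.45, 485: 0.32, 490: 0.22, 495: 0.16, 500: 0.10,
    }
    vals = np.empty_like(wl)
    for i, w in enumerate(wl):
        wi = int(round(w))
        if wi <= 380:
            vals[i] = 0.01
        elif wi in explicit:
            vals[i] = explicit[wi]
        elif 500 < wi <= 600:
            vals[i] = 10.0 ** ((450.0 - wi) / 50.0)
        else:  # 600 < wi <= 700
            vals[i] = 0.001
    return wl, vals


def build_all() -> dict[str, tuple[np.ndarray, np.ndarray, dict[str, str]]]:
    """Return ``name -> (wavelengths, weights, metadata)`` for all seven functions."""
    grid = WavelengthGrid.uniform(380.0, 780.0, 1.0).values
    tau_lens = lens_transmittance(grid, STANDARD_OBSERVER_AGE)
    tau_mac = macular_transmittance(grid)

    out: dict[str, tuple[np.ndarray, np.ndarray, dict[str, str]]] = {}
    for name, peak in PIGMENT_PEAKS_NM.items():
        pigment = govardovskii_template(grid, peak)
        weights = pigment * tau_lens
        if name.endswith("cone_opic"):
            weights = weights * tau_mac
        weights = weights / weights.max()
        out[name] = (
            grid,
            weights,
            {
                "name": name,
                "description": (
                    "synthetic stand-in corneal spectral sensitivity: "
                    f"Govardovskii A1 pigment template (peak {peak:g} nm) x "
                    "32-year lens transmittance"
                    + (" x macular transmittance" if name.endswith("cone_opic") else "")
                ),
                "pigment_peak_nm": f"{peak:g}",
            },
        )

    v = np.interp(grid, np.arange(380.0, 781.0, 5.0), _V_LAMBDA_5NM)
    out["photopic_V"] = (
        grid,
        v,
        {
            "name": "photopic_V",
            "description": (
                "photopic luminous efficiency V(lambda); synthetic stand-in "
                "transcribed from the widely published 5-nm tabulation, "
                "linearly interpolated to 1 nm (peak 1.0 at 555 nm)"
            ),
        },
    )

    bw, bv = _blue_light_hazard_table()
    out["blue_light_hazard"] = (
        bw,
        bv,
        {
            "name": "blue_light_hazard",
            "description": (
                "retinal blue-light photochemical hazard B(lambda); synthetic "
                "stand-in following the widely published piecewise tabulation, "
                "native 5-nm grid 300-700 nm, unit peak 435-440 nm"
            ),
        },
    )
    return out


def write_tables(data_dir: Path = DATA_DIR) -> dict[str, str]:
    """Write one ASCII table per function plus a sha256 checksum manifest."""
    data_dir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name, (wl, weights, meta) in build_all().items():
        fname = f"synthetic_{name}.csv"
        lines = [f"# {k}: {v}" for k, v in meta.items()]
        lines.append("# columns: wavelength_nm,weight")
        lines += [f"{repr(float(w))},{repr(float(x))}" for w, x in zip(wl, weights)]
        text = "\n".join(lines) + "\n"
        (data_dir / fname).write_text(text, encoding="ascii")
        checksums[fname] = hashlib.sha256(text.encode("ascii")).hexdigest()
    (data_dir / "checksums.json").write_text(
        json.dumps(checksums, indent=1, sort_keys=True) + "\n", encoding="ascii"
    )
    return checksums


if __name__ == "__main__":
    for f, h in write_tables().items():
        print(f, h)
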