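"""Synthetic SPDs and exposure records for testing and demonstration.

Emulates the lab sources a spectroradiometer would meet — Planckian
(incandescent/daylight-like) radiators, multi-primary LED mixtures as
Gaussian bands, and monochromatic lines — plus fully populated and
deliberately deficient exposure records for exercising the compliance
validator.  Everything is deterministic given its parameters (and seed,
where randomness is involved); fixture parameters are recorded in the SPD
metadata for provenance.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exposure_report import (
    ExposureRecord,
    GeometrySpec,
    MeasurementMeta,
    ObserverMeta,
    SPDRef,
    TimingSpec,
)
from .quantities import alpha_opic_panel, panel_to_dict
from .spectral_core import (
    Kind,
    SpectralMeasurement,
    WavelengthGrid,
    standard_grid,
    write_spd_tabulated,
)

__all__ = [
    "planckian_spd",
    "gaussian_led_spd",
    "monochromatic_spd",
    "random_gaussian_led_spd",
    "metamer_pair",
    "complete_record",
    "deficient_record",
    "BOX1_OMISSION_LABELS",
]

_H = 6.62607015e-34
_C = 299_792_458.0
_KB = 1.380649e-23


def planckian_spd(
    temperature_k: float,
    scale_factor: float = 1.0,
    kind: Kind = Kind.RADIANCE,
    label: str = "",
) -> SpectralMeasurement:
    """Planck's-law spectral shape on the 380–780 nm 1-nm grid.

    For radiance kind the unscaled values are the absolute blackbody spectral
    radiance in W·m⁻²·sr⁻¹·nm⁻¹; ``scale_factor`` dims or boosts the source.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0 K")
    if scale_factor < 0:
        raise ValueError("scale factor must be >= 0")
    grid = standard_grid()
    lam = grid.values * 1e-9
    radiance_per_m = (2.0 * _H * _C**2 / lam**5) / np.expm1(_H * _C / (lam * _KB * temperature_k))
    values = radiance_per_m * 1e-9 * scale_factor  # per nm
    return SpectralMeasurement(
        grid=grid,
        values=values,
        kind=kind,
        label=label or f"Planckian {temperature_k:g} K",
        metadata={
            "fixture": "planckian",
            "temperature_K": f"{temperature_k:g}",
            "scale_factor": f"{scale_factor:g}",
        },
    )


def gaussian_led_spd(
    primaries: Sequence[tuple[float, float, float]],
    kind: Kind = Kind.IRRADIANCE,
    label: str = "",
) -> SpectralMeasurement:
    """Multi-primary LED mixture: sum of Gaussian bands on the standard grid.

    Each primary is (peak nm, FWHM nm, weight), where the weight is the
    band-integrated power of that primary (W/m² or W/(m²·sr)); bands are
    area-normalized Gaussians, so the total integrated power is the sum of
    the weights up to window truncation.
    """
    if not primaries:
        raise ValueError("at least one LED primary is required")
    grid = standard_grid()
    values = np.zeros(len(grid))
    for peak, fwhm, weight in primaries:
        if fwhm <= 0:
            raise ValueError("FWHM must be > 0 nm")
        if weight < 0:
            raise ValueError("primary weights must be >= 0")
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        values += weight * np.exp(-0.5 * ((grid.values - peak) / sigma) ** 2) / (
            sigma * np.sqrt(2.0 * np.pi)
        )
    desc = ";".join(f"({p:g},{f:g},{w:g})" for p, f, w in primaries)
    return SpectralMeasurement(
        grid=grid,
        values=values,
        kind=kind,
        label=label or "Gaussian LED mixture",
        metadata={"fixture": "gaussian_led_mix", "primaries_peak_fwhm_weight": desc},
    )


def monochromatic_spd(
    wavelength_nm: float,
    band_power: float,
    kind: Kind = Kind.IRRADIANCE,
    label: str = "",
) -> SpectralMeasurement:
    """Single-bin line on the standard grid with exact band-integrated power.

    The single sample is ``band_power / Δλ`` so that any rectangle-sum
    integral recovers ``band_power`` exactly; off-grid wavelengths are an
    error (no sub-bin placement).
    """
    grid = standard_grid()
    idx = (np.abs(grid.values - wavelength_nm)).argmin()
    if abs(grid.values[idx] - wavelength_nm) > 1e-9:
        raise ValueError(
            f"wavelength {wavelength_nm} nm is not on the 1-nm 380–780 nm grid"
        )
    values = np.zeros(len(grid))
    values[idx] = band_power / grid.step
    return SpectralMeasurement(
        grid=grid,
        values=values,
        kind=kind,
        label=label or f"monochromatic {wavelength_nm:g} nm",
        metadata={
            "fixture": "monochromatic",
            "wavelength_nm": f"{wavelength_nm:g}",
            "band_power": f"{band_power:g}",
        },
    )


def random_gaussian_led_spd(
    seed: int,
    kind: Kind = Kind.IRRADIANCE,
) -> SpectralMeasurement:
    """A seeded random RGB(W)-like LED mixture, for oracle sweeps.

    Emulates realistic multi-primary lab sources: one blue, one green and one
    red primary with randomized peaks, bandwidths and weights, plus an
    optional fourth broadband primary — so every photoreceptor class receives
    non-negligible drive, as it does from real panels.
    """
    rng = np.random.default_rng(seed)
    primaries = [
        (float(rng.uniform(440.0, 480.0)), float(rng.uniform(15.0, 30.0)), float(rng.uniform(0.2, 1.0))),
        (float(rng.uniform(510.0, 560.0)), float(rng.uniform(25.0, 50.0)), float(rng.uniform(0.2, 1.0))),
        (float(rng.uniform(600.0, 660.0)), float(rng.uniform(15.0, 35.0)), float(rng.uniform(0.2, 1.0))),
    ]
    if rng.random() < 0.5:
        primaries.append(
            (float(rng.uniform(420.0, 680.0)), float(rng.uniform(30.0, 60.0)), float(rng.uniform(0.1, 0.5)))
        )
    spd = gaussian_led_spd(primaries, kind=kind, label=f"random LED mix (seed {seed})")
    return SpectralMeasurement(
        grid=spd.grid,
        values=spd.values,
        kind=spd.kind,
        label=spd.label,
        metadata={**dict(spd.metadata), "seed": str(seed)},
    )


def metamer_pair(kind: Kind = Kind.IRRADIANCE) -> tuple[SpectralMeasurement, SpectralMeasurement]:
    """Two spectra with matched photopic value but very different melanopic value.

    Spectrum A is a blue-rich three-primary mixture; spectrum B is a
    long-wavelength two-primary mixture scaled so its photopic value equals
    A's exactly.  Illuminance alone cannot distinguish the two, but their
    melanopic values differ severalfold — the reason illuminance-only
    reporting is insufficient.
    """
    a = gaussian_led_spd(
        [(455.0, 20.0, 0.35), (535.0, 25.0, 0.35), (625.0, 25.0, 0.30)],
        kind=kind,
        label="metamer A (blue-rich)",
    )
    b0 = gaussian_led_spd(
        [(545.0, 30.0, 0.5), (610.0, 30.0, 0.5)],
        kind=kind,
        label="metamer B (long-wavelength)",
    )
    phot_a = alpha_opic_panel(a).photopic
    phot_b = alpha_opic_panel(b0).photopic
    s = phot_a / phot_b
    b = SpectralMeasurement(
        grid=b0.grid, values=b0.values * s, kind=b0.kind, label=b0.label,
        metadata={**dict(b0.metadata), "photopic_matched_to": a.label},
    )
    return a, b


# ---------------------------------------------------------------------------
# Exposure-record fixtures

BOX1_OMISSION_LABELS = frozenset(f"item{i}" for i in range(1, 8))


def complete_record(workdir: str | Path) -> ExposureRecord:
    """A fully populated exposure record that validates 7/7.

    Writes the stimulus and background tabulated spectra into ``workdir`` and
    references them from the manifest.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    stimulus = gaussian_led_spd(
        [(455.0, 18.0, 0.25), (520.0, 30.0, 0.45), (630.0, 20.0, 0.30)],
        kind=Kind.IRRADIANCE,
        label="LED panel stimulus",
    )
    background = planckian_spd(2700.0, scale_factor=2e-7, kind=Kind.IRRADIANCE,
                               label="dim incandescent background")

    stim_path = workdir / "stimulus_spd.csv"
    bg_path = workdir / "background_spd.csv"
    stim_path.write_text(write_spd_tabulated(stimulus), encoding="ascii")
    bg_path.write_text(write_spd_tabulated(background), encoding="ascii")

    panels = {
        "stimulus": panel_to_dict(alpha_opic_panel(stimulus)),
        "background": panel_to_dict(alpha_opic_panel(background)),
    }

    tz = timezone(timedelta(hours=1))
    onset = datetime(2019, 6, 1, 22, 0, 0, tzinfo=tz)
    record = ExposureRecord(
        label="synthetic laboratory exposure",
        stimulus_spd=SPDRef(
            path=stim_path.name, kind="spectral_irradiance", provenance="measured",
            label=stimulus.label,
            geometry="vertical irradiance at the cornea, 0 deg, 0.6 m from the panel",
        ),
        background_spd=SPDRef(
            path=bg_path.name, kind="spectral_irradiance", provenance="measured",
            label=background.label,
            geometry="vertical irradiance at eye level, 0 deg, centre of the room",
        ),
        spectra_files=[stim_path.name, bg_path.name],
        panels=panels,
        timing=TimingSpec(
            clock_onset=onset,
            clock_offset=onset + timedelta(hours=2),
            pattern="constant",
        ),
        geometry=GeometrySpec(
            width_m=0.6, height_m=0.4, distance_m=0.6, shape="rectangular panel",
            observer_position="seated, eye level with panel centre",
            view_angle="0 deg (straight-on)",
        ),
        measurement=MeasurementMeta(
            instrument_brand="SynthOptics",
            instrument_model="SR-1000",
            sensor="back-thinned CCD",
            wavelength_sampling_nm=1.0,
            spectral_bandwidth_nm=2.0,
            reporting_range_nm=(380.0, 780.0),
            measurement_geometry="cosine-corrected head at the observer's eye position",
        ),
        observer=ObserverMeta(age_years=32.0, eyes_open=2, field_diameter_deg=10.0),
        reported_photopic_illuminance_lux=alpha_opic_panel(stimulus).photopic,
    )
    return record.with_base_dir(workdir)


def deficient_record(omissions: Iterable[str], workdir: str | Path) -> ExposureRecord:
    """A complete record with exactly the named minimum-reporting elements removed.

    ``omissions`` is a subset of {"item1", ..., "item7"}; each label removes
    the element owned by that guideline item (stimulus SPD, background SPD,
    tabulated files, panels, timing, geometry, measurement metadata).
    """
    omissions = set(omissions)
    unknown = omissions - BOX1_OMISSION_LABELS
    if unknown:
        raise ValueError(f"unknown omission label(s): {sorted(unknown)}")
    record = complete_record(workdir)
    if "item1" in omissions:
        record.stimulus_spd = None
    if "item2" in omissions:
        record.background_spd = None
    if "item3" in omissions:
        record.spectra_files = []
    if "item4" in omissions:
        record.panels = {}
    if "item5" in omissions:
        record.timing = None
    if "item6" in omissions:
        record.geometry = None
    if "item7" in omissions:
        record.measurement = None
    return record
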