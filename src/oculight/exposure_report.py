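"""Executable minimum reporting guidelines for light-exposure experiments.

A light-exposure record bundles the stimulus and background SPDs with timing,
spatial and measurement metadata.  Seven minimum items make a report
complete:

1. stimulus SPD from the observer's point of view, at a known angle/distance;
2. background SPD from the observer's point of view;
3. spectra available in tabulated ASCII form;
4. alpha-opic (ir)radiances and (il)luminance;
5. timing properties (clock time, duration, pattern);
6. spatial properties (arrangement and extent);
7. measurement conditions and equipment.

This module defines the manifest schema (pydantic; JSON on disk, YAML
accepted on input), validates a record against the seven items, and renders
a standardized report as Markdown plus machine-readable JSON.

Verdict semantics: a missing element fails its item; an element that is
present but incomplete warns.  Validation is monotone — adding information
never turns a pass into a fail.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, PrivateAttr, field_validator, model_validator

from .observer_geometry import visual_angle
from .quantities import ALPHA_OPIC_NAMES
from .spectral_core import Kind, SpdParseError, SpectralMeasurement, WavelengthGrid, read_spd

__all__ = [
    "BOX1_TITLES",
    "SPDRef",
    "TimingSpec",
    "GeometrySpec",
    "MeasurementMeta",
    "ObserverMeta",
    "ExposureRecord",
    "ItemVerdict",
    "ComplianceReport",
    "load_record",
    "validate_record",
    "render_report",
    "manifest_schema",
]

BOX1_TITLES = {
    1: "Stimulus spectral power distribution from the observer's point of view",
    2: "Background spectral power distribution from the observer's point of view",
    3: "Spectra available in tabulated form",
    4: "Alpha-opic (ir)radiances and (il)luminance",
    5: "Timing properties of the stimulus",
    6: "Spatial properties of the stimulus",
    7: "Measurement conditions and equipment",
}


class SPDRef(BaseModel):
    """Reference to a spectrum: a tabulated file path or inline arrays.

    ``geometry`` records the angle and distance from the source at which the
    spectrum was taken — required for a full pass of items 1 and 2.
    """

    path: Optional[str] = None
    wavelength_nm: Optional[list[float]] = None
    value: Optional[list[float]] = None
    kind: Literal["spectral_irradiance", "spectral_radiance"] = "spectral_irradiance"
    provenance: Literal["measured", "manufacturer"] = "measured"
    label: str = ""
    geometry: str = ""

    @model_validator(mode="after")
    def _some_source(self) -> "SPDRef":
        inline = self.wavelength_nm is not None and self.value is not None
        if self.path is None and not inline:
            raise ValueError("SPD reference needs either a path or inline wavelength/value arrays")
        return self

    def resolve(self, base_dir: Path | None = None) -> SpectralMeasurement:
        if self.path is not None:
            p = Path(self.path)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            spd = read_spd(str(p), Kind(self.kind))
            return SpectralMeasurement(
                grid=spd.grid, values=spd.values, kind=spd.kind,
                label=self.label or spd.label, provenance=self.provenance,
                metadata=spd.metadata,
            )
        return SpectralMeasurement(
            grid=WavelengthGrid.from_values(np.asarray(self.wavelength_nm)),
            values=np.asarray(self.value),
            kind=Kind(self.kind),
            label=self.label,
            provenance=self.provenance,
        )


class TimingSpec(BaseModel):
    """Clock times, duration and temporal pattern of the exposure."""

    clock_onset: datetime
    clock_offset: datetime
    pattern: Literal["constant", "flash_train", "dynamic"] = "constant"
    flash_duration_s: Optional[float] = Field(None, gt=0)
    inter_stimulus_interval_s: Optional[float] = Field(None, gt=0)
    device_refresh_rate_hz: Optional[float] = Field(None, gt=0)
    mean_light_reference: Optional[str] = None

    @field_validator("clock_onset", "clock_offset")
    @classmethod
    def _tz_required(cls, v: datetime) -> datetime:
        if v.tzinfo is None:
            raise ValueError("clock times must carry a timezone (ISO 8601 with offset)")
        return v

    @model_validator(mode="after")
    def _offset_after_onset(self) -> "TimingSpec":
        if self.clock_offset <= self.clock_onset:
            raise ValueError("clock_offset must be after clock_onset")
        return self

    @property
    def duration_s(self) -> float:
        return (self.clock_offset - self.clock_onset).total_seconds()

    def problems(self) -> list[str]:
        """Pattern-conditional completeness checks (warn-level)."""
        out = []
        if self.pattern == "flash_train":
            if self.flash_duration_s is None:
                out.append("flash_train pattern without flash_duration_s")
            if self.inter_stimulus_interval_s is None:
                out.append("flash_train pattern without inter_stimulus_interval_s")
        if self.pattern == "dynamic":
            if self.device_refresh_rate_hz is None:
                out.append("dynamic pattern without device_refresh_rate_hz")
            if self.mean_light_reference is None:
                out.append("dynamic pattern without a mean-light SPD reference")
        return out


class GeometrySpec(BaseModel):
    """Spatial arrangement: source extent, observer distance and view angle."""

    width_m: float = Field(gt=0)
    height_m: float = Field(gt=0)
    distance_m: float = Field(gt=0)
    shape: str = ""
    observer_position: str = ""
    view_angle: str = ""

    def visual_angles_deg(self) -> tuple[float, float]:
        return (
            visual_angle(self.width_m, self.distance_m),
            visual_angle(self.height_m, self.distance_m),
        )


class MeasurementMeta(BaseModel):
    """Instrument and measurement-condition metadata."""

    instrument_brand: str = ""
    instrument_model: str = ""
    sensor: str = ""
    wavelength_sampling_nm: Optional[float] = Field(None, gt=0)
    spectral_bandwidth_nm: Optional[float] = Field(None, gt=0)
    reporting_range_nm: Optional[tuple[float, float]] = None
    measurement_geometry: str = ""

    @field_validator("reporting_range_nm")
    @classmethod
    def _ordered(cls, v):
        if v is not None and not v[0] < v[1]:
            raise ValueError("reporting range lower bound must be below upper bound")
        return v

    def missing_fields(self) -> list[str]:
        out = [
            name
            for name in ("instrument_brand", "instrument_model", "sensor", "measurement_geometry")
            if not getattr(self, name)
        ]
        out += [
            name
            for name in ("wavelength_sampling_nm", "spectral_bandwidth_nm", "reporting_range_nm")
            if getattr(self, name) is None
        ]
        return out


class ObserverMeta(BaseModel):
    """Optional observer-side context (ages, pupil, eyes open)."""

    age_years: Optional[float] = Field(None, gt=0)
    eyes_open: Optional[int] = Field(None, ge=1, le=2)
    field_diameter_deg: Optional[float] = Field(None, gt=0)
    pupil_diameter_mm: Optional[float] = Field(None, gt=0)
    dilation_agent: str = ""
    percent_eyes_open: str = ""  # free-text estimate; no standard procedure exists


class ExposureRecord(BaseModel):
    """One light-exposure condition: spectra, derived panels and metadata.

    All sections are optional at the schema level so that deficient records
    can be *validated* (producing per-item fails) rather than rejected at
    parse time; genuinely malformed sections still raise with the field name.
    """

    stimulus_spd: Optional[SPDRef] = None
    background_spd: Optional[SPDRef] = None
    spectra_files: list[str] = Field(default_factory=list)
    panels: dict[str, dict[str, float | str]] = Field(default_factory=dict)
    timing: Optional[TimingSpec] = None
    geometry: Optional[GeometrySpec] = None
    measurement: Optional[MeasurementMeta] = None
    observer: Optional[ObserverMeta] = None
    reported_photopic_illuminance_lux: Optional[float] = Field(None, ge=0)
    photograph_path: Optional[str] = None
    safety: Optional[dict] = None
    label: str = ""

    _base_dir: Optional[Path] = PrivateAttr(default=None)

    @property
    def base_dir(self) -> Optional[Path]:
        return self._base_dir

    def with_base_dir(self, base_dir: Path | str) -> "ExposureRecord":
        self._base_dir = Path(base_dir)
        return self


class ItemVerdict(BaseModel):
    item: int
    title: str
    verdict: Literal["pass", "fail", "warn"]
    message: str


class ComplianceReport(BaseModel):
    """Per-item verdicts against the seven minimum reporting guidelines."""

    items: list[ItemVerdict]

    @model_validator(mode="after")
    def _exactly_seven(self) -> "ComplianceReport":
        if len(self.items) != 7:
            raise ValueError("a compliance report has exactly 7 items")
        return self

    @property
    def n_pass(self) -> int:
        return sum(1 for i in self.items if i.verdict == "pass")

    @property
    def n_warn(self) -> int:
        return sum(1 for i in self.items if i.verdict == "warn")

    @property
    def n_fail(self) -> int:
        return sum(1 for i in self.items if i.verdict == "fail")

    @property
    def all_pass(self) -> bool:
        return self.n_pass == 7

    def summary(self) -> str:
        return f"{self.n_pass}/7 pass, {self.n_warn} warn, {self.n_fail} fail"


def load_record(path: str | Path) -> ExposureRecord:
    """Load a manifest from JSON (``.json``) or YAML (``.yaml``/``.yml``)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    try:
        record = ExposureRecord.model_validate(data)
    except Exception as exc:  # re-raise with the file path attached
        raise ValueError(f"cannot parse exposure manifest {path}: {exc}") from exc
    return record.with_base_dir(path.parent)


# ---------------------------------------------------------------------------
# Compliance validation


def _resolve(ref: SPDRef, base_dir: Optional[Path]) -> tuple[Optional[SpectralMeasurement], str]:
    try:
        return ref.resolve(base_dir), ""
    except (OSError, SpdParseError, ValueError) as exc:
        return None, str(exc)


def _check_spd_item(
    item: int,
    ref: Optional[SPDRef],
    record: ExposureRecord,
    what: str,
) -> ItemVerdict:
    if ref is None:
        return ItemVerdict(
            item=item, title=BOX1_TITLES[item], verdict="fail",
            message=f"no {what} SPD reported",
        )
    spd, err = _resolve(ref, record.base_dir)
    if spd is None:
        return ItemVerdict(
            item=item, title=BOX1_TITLES[item], verdict="warn",
            message=f"{what} SPD reference present but unreadable: {err}",
        )
    notes = []
    verdict = "pass"
    if not ref.geometry:
        verdict = "warn"
        notes.append("measurement angle/distance from the source not specified")
    if (
        item == 1
        and ref.provenance == "manufacturer"
        and record.reported_photopic_illuminance_lux is None
    ):
        verdict = "warn"
        notes.append(
            "manufacturer-tabulated spectrum without an in-situ photopic "
            "illuminance measurement"
        )
    msg = f"{what} SPD present ({len(spd.grid)} samples, {ref.kind})"
    if notes:
        msg += "; " + "; ".join(notes)
    return ItemVerdict(item=item, title=BOX1_TITLES[item], verdict=verdict, message=msg)


def _panel_complete(panel: dict[str, float | str]) -> bool:
    keys = list(panel)
    has_alpha = all(any(k.startswith(name) for k in keys) for name in ALPHA_OPIC_NAMES)
    has_photopic = any(k.startswith("photopic") for k in keys)
    return has_alpha and has_photopic


def validate_record(record: ExposureRecord) -> ComplianceReport:
    """Check an exposure record against the seven minimum reporting items."""
    items: list[ItemVerdict] = []

    items.append(_check_spd_item(1, record.stimulus_spd, record, "stimulus"))
    items.append(_check_spd_item(2, record.background_spd, record, "background"))

    # item 3: tabulated exports exist and re-parse
    if not record.spectra_files:
        items.append(ItemVerdict(
            item=3, title=BOX1_TITLES[3], verdict="fail",
            message="no tabulated spectrum files listed",
        ))
    else:
        broken = []
        for f in record.spectra_files:
            p = Path(f)
            if record.base_dir is not None and not p.is_absolute():
                p = record.base_dir / f
            try:
                read_spd(str(p), Kind.IRRADIANCE)
            except (OSError, SpdParseError) as exc:
                broken.append(f"{f}: {exc}")
        if broken:
            items.append(ItemVerdict(
                item=3, title=BOX1_TITLES[3], verdict="warn",
                message="listed tabulated files do not re-parse: " + "; ".join(broken),
            ))
        else:
            items.append(ItemVerdict(
                item=3, title=BOX1_TITLES[3], verdict="pass",
                message=f"{len(record.spectra_files)} tabulated ASCII file(s) re-parse cleanly",
            ))

    # item 4: alpha-opic panel per reported SPD
    needed = [n for n, r in (("stimulus", record.stimulus_spd), ("background", record.background_spd)) if r is not None]
    if not record.panels:
        items.append(ItemVerdict(
            item=4, title=BOX1_TITLES[4], verdict="fail",
            message="no alpha-opic panels reported",
        ))
    else:
        incomplete = [k for k, p in record.panels.items() if not _panel_complete(p)]
        missing = [n for n in needed if n not in record.panels]
        if incomplete or missing:
            bits = []
            if missing:
                bits.append("no panel for: " + ", ".join(missing))
            if incomplete:
                bits.append("incomplete panel(s): " + ", ".join(incomplete))
            items.append(ItemVerdict(
                item=4, title=BOX1_TITLES[4], verdict="warn", message="; ".join(bits),
            ))
        else:
            items.append(ItemVerdict(
                item=4, title=BOX1_TITLES[4], verdict="pass",
                message="five alpha-opic values plus photopic quantity present per SPD",
            ))

    # item 5: timing
    if record.timing is None:
        items.append(ItemVerdict(
            item=5, title=BOX1_TITLES[5], verdict="fail",
            message="no timing specification",
        ))
    else:
        probs = record.timing.problems()
        if probs:
            items.append(ItemVerdict(
                item=5, title=BOX1_TITLES[5], verdict="warn", message="; ".join(probs),
            ))
        else:
            items.append(ItemVerdict(
                item=5, title=BOX1_TITLES[5], verdict="pass",
                message=(
                    f"{record.timing.pattern} exposure, "
                    f"{record.timing.duration_s:.0f} s from "
                    f"{record.timing.clock_onset.isoformat()}"
                ),
            ))

    # item 6: spatial properties with computed visual angle
    if record.geometry is None:
        items.append(ItemVerdict(
            item=6, title=BOX1_TITLES[6], verdict="fail",
            message="no stimulus geometry",
        ))
    else:
        h, v = record.geometry.visual_angles_deg()
        items.append(ItemVerdict(
            item=6, title=BOX1_TITLES[6], verdict="pass",
            message=(
                f"size {record.geometry.width_m:g} x {record.geometry.height_m:g} m at "
                f"{record.geometry.distance_m:g} m -> visual angle {h:.2f} x {v:.2f} deg"
            ),
        ))

    # item 7: measurement conditions and equipment
    if record.measurement is None:
        items.append(ItemVerdict(
            item=7, title=BOX1_TITLES[7], verdict="fail",
            message="no measurement metadata",
        ))
    else:
        missing = record.measurement.missing_fields()
        if missing:
            items.append(ItemVerdict(
                item=7, title=BOX1_TITLES[7], verdict="warn",
                message="measurement metadata incomplete: " + ", ".join(missing),
            ))
        else:
            items.append(ItemVerdict(
                item=7, title=BOX1_TITLES[7], verdict="pass",
                message=(
                    f"{record.measurement.instrument_brand} "
                    f"{record.measurement.instrument_model} ({record.measurement.sensor})"
                ),
            ))

    return ComplianceReport(items=items)


# ---------------------------------------------------------------------------
# Rendering


_MARK = {"pass": "PASS", "warn": "WARN", "fail": "FAIL"}


def render_report(
    record: ExposureRecord,
    compliance: ComplianceReport,
    timestamp: Optional[str] = None,
) -> tuple[str, dict]:
    """Render a record as (Markdown document, machine-readable JSON dict).

    Deterministic: the same record renders byte-identically; a timestamp
    appears only when injected explicitly.
    """
    lines: list[str] = []
    title = record.label or "Light-exposure report"
    lines.append(f"# {title}")
    if timestamp:
        lines.append(f"\nGenerated: {timestamp}")

    lines.append("\n## Spectra")
    for name, ref in (("Stimulus", record.stimulus_spd), ("Background", record.background_spd)):
        if ref is None:
            lines.append(f"- {name}: not reported")
        else:
            where = ref.path if ref.path else "inline"
            geom = f"; geometry: {ref.geometry}" if ref.geometry else ""
            lines.append(f"- {name}: {where} ({ref.kind}, {ref.provenance}{geom})")
    if record.spectra_files:
        lines.append("- Tabulated files: " + ", ".join(record.spectra_files))

    if record.panels:
        lines.append("\n## Alpha-opic panels")
        for label, panel in record.panels.items():
            lines.append(f"\n### {label}")
            for k, v in panel.items():
                lines.append(f"- {k}: {v:.6g}" if isinstance(v, float) else f"- {k}: {v}")

    if record.timing is not None:
        t = record.timing
        lines.append("\n## Timing")
        lines.append(f"- onset: {t.clock_onset.isoformat()}")
        lines.append(f"- offset: {t.clock_offset.isoformat()}")
        lines.append(f"- duration: {t.duration_s:.0f} s")
        lines.append(f"- pattern: {t.pattern}")
        if t.flash_duration_s is not None:
            lines.append(f"- flash duration: {t.flash_duration_s:g} s")
        if t.inter_stimulus_interval_s is not None:
            lines.append(f"- inter-stimulus interval: {t.inter_stimulus_interval_s:g} s")
        if t.device_refresh_rate_hz is not None:
            lines.append(f"- device refresh rate: {t.device_refresh_rate_hz:g} Hz")
        if t.mean_light_reference:
            lines.append(f"- mean-light SPD: {t.mean_light_reference}")

    if record.geometry is not None:
        g = record.geometry
        h, v = g.visual_angles_deg()
        lines.append("\n## Spatial properties")
        lines.append(f"- source size: {g.width_m:g} x {g.height_m:g} m ({g.shape or 'shape unspecified'})")
        lines.append(f"- viewing distance: {g.distance_m:g} m")
        lines.append(f"- visual angle: {h:.2f} x {v:.2f} deg")
        if g.observer_position:
            lines.append(f"- observer position: {g.observer_position}")
        if g.view_angle:
            lines.append(f"- view angle: {g.view_angle}")

    if record.measurement is not None:
        m = record.measurement
        lines.append("\n## Measurement conditions")
        lines.append(f"- instrument: {m.instrument_brand} {m.instrument_model} ({m.sensor})")
        if m.wavelength_sampling_nm is not None:
            lines.append(f"- wavelength sampling: {m.wavelength_sampling_nm:g} nm")
        if m.spectral_bandwidth_nm is not None:
            lines.append(f"- spectral bandwidth: {m.spectral_bandwidth_nm:g} nm")
        if m.reporting_range_nm is not None:
            lines.append(
                f"- reporting range: {m.reporting_range_nm[0]:g}-{m.reporting_range_nm[1]:g} nm"
            )
        if m.measurement_geometry:
            lines.append(f"- measurement geometry: {m.measurement_geometry}")

    optional = []
    if record.observer is not None:
        o = record.observer
        if o.age_years is not None:
            optional.append(f"observer age: {o.age_years:g} y")
        if o.eyes_open is not None:
            optional.append(f"eyes open: {o.eyes_open}")
        if o.pupil_diameter_mm is not None:
            optional.append(f"measured pupil: {o.pupil_diameter_mm:g} mm")
        if o.percent_eyes_open:
            optional.append(f"percent eyes open: {o.percent_eyes_open}")
    if record.photograph_path:
        optional.append(f"photograph/sketch: {record.photograph_path}")
    if record.safety is not None:
        optional.append(
            f"safety screen: {record.safety.get('verdict', 'n/a')}"
        )
    if optional:
        lines.append("\n## Optional items")
        lines += [f"- {x}" for x in optional]

    lines.append("\n## Compliance with the minimum reporting guidelines")
    lines.append(f"\nSummary: {compliance.summary()}")
    lines.append("")
    lines.append("| # | Item | Verdict | Notes |")
    lines.append("|---|------|---------|-------|")
    for item in compliance.items:
        lines.append(
            f"| {item.item} | {item.title} | {_MARK[item.verdict]} | {item.message} |"
        )

    markdown = "\n".join(lines) + "\n"
    payload = {
        "record": json.loads(record.model_dump_json(exclude_none=True)),
        "compliance": json.loads(compliance.model_dump_json()),
        "summary": compliance.summary(),
    }
    if timestamp:
        payload["generated"] = timestamp
    return markdown, payload


def manifest_schema() -> dict:
    """JSON schema of the exposure-record manifest, for mechanical validation."""
    return ExposureRecord.model_json_schema()
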