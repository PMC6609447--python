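"""Canonical spectral-power-distribution data model and ASCII I/O.

The stimulus that matters for retinally mediated responses is the spectral
power distribution (SPD) of light reaching the eye, reported either as
spectral irradiance at the cornea (W·m⁻²·nm⁻¹) or as spectral radiance of an
emitting surface (W·m⁻²·sr⁻¹·nm⁻¹).  This module provides the wavelength-grid
and SPD containers used everywhere else, validated reading/writing of the
uncompressed delimited-ASCII exchange format, piecewise-linear resampling and
linear scaling.

Exchange format: optional ``# key: value`` header lines followed by two
numeric columns (wavelength in nm, spectral value).  Comma, tab and semicolon
delimiters are auto-detected on read; exports are comma-separated.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Mapping

import numpy as np

__all__ = [
    "Kind",
    "WavelengthGrid",
    "SpectralMeasurement",
    "SpdParseError",
    "read_spd",
    "write_spd_tabulated",
    "resample",
    "scale",
    "standard_grid",
    "EXPORT_RANGE_NM",
    "EXPORT_SPACING_RANGE_NM",
]

#: Default tabulation window for exports, nm.
EXPORT_RANGE_NM = (380.0, 780.0)
#: Allowed nominal spacing for tabulated exports, nm.
EXPORT_SPACING_RANGE_NM = (1.0, 10.0)

_UNIFORM_TOL_NM = 1e-6


class Kind(str, Enum):
    """Physical quantity carried by an SPD; fixes the units of derived scalars."""

    IRRADIANCE = "spectral_irradiance"  # W·m⁻²·nm⁻¹
    RADIANCE = "spectral_radiance"  # W·m⁻²·sr⁻¹·nm⁻¹

    @property
    def spectral_unit(self) -> str:
        return "W/(m^2 nm)" if self is Kind.IRRADIANCE else "W/(m^2 sr nm)"


class SpdParseError(ValueError):
    """Raised when a tabulated spectrum file cannot be parsed."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength samples in nm.

    ``step`` is the nominal spacing and is only set for uniform grids
    (successive differences within 1e-6 nm of the nominal value).
    """

    values: np.ndarray
    step: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavelengths must be finite and > 0 nm")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            bad = int(np.argmax(np.diff(v) <= 0)) + 1
            raise ValueError(f"wavelengths not strictly increasing at index {bad}")
        if self.step is not None:
            if v.size > 1:
                dev = np.max(np.abs(np.diff(v) - self.step))
                if dev >= _UNIFORM_TOL_NM:
                    raise ValueError(
                        f"grid declared uniform with step {self.step} nm but successive "
                        f"differences deviate by up to {dev:g} nm"
                    )

    @classmethod
    def uniform(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n), step=step)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavelengthGrid":
        """Build a grid, inferring ``step`` when the samples are uniform."""
        v = np.asarray(values, dtype=float)
        step = None
        if v.size > 1:
            d = np.diff(v)
            if np.max(np.abs(d - d[0])) < _UNIFORM_TOL_NM:
                step = float(d[0])
        return cls(v, step=step)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


@dataclass(frozen=True)
class SpectralMeasurement:
    """An SPD: a wavelength grid, spectral values, and a quantity kind.

    Negative samples (instrument noise around zero) are retained and flagged
    via :attr:`has_negative_values`; use :meth:`clipped_nonnegative` to zero
    them explicitly when a derived quantity requires it.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: Kind
    label: str = ""
    provenance: str = "measured"  # "measured" or "manufacturer"
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.values.shape:
            raise ValueError(
                f"values length {v.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite")
        if self.provenance not in ("measured", "manufacturer"):
            raise ValueError("provenance must be 'measured' or 'manufacturer'")
        object.__setattr__(self, "kind", Kind(self.kind))

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    @property
    def has_negative_values(self) -> bool:
        return bool(np.any(self.values < 0))

    def clipped_nonnegative(self) -> "SpectralMeasurement":
        """Return a copy with negative samples clipped to zero (explicit opt-in)."""
        return replace(self, values=np.clip(self.values, 0.0, None))


def standard_grid() -> WavelengthGrid:
    """The 380–780 nm, 1-nm reporting grid."""
    return WavelengthGrid.uniform(*EXPORT_RANGE_NM, 1.0)


# ---------------------------------------------------------------------------
# ASCII I/O


def _detect_delimiter(line: str) -> str:
    for d in (",", "\t", ";"):
        if d in line:
            return d
    return ","  # single-column fallback; parsing will fail with a clear error


def read_spd(source: str | IO[str], kind: Kind | str) -> SpectralMeasurement:
    """Parse a delimited-ASCII tabulated spectrum.

    ``source`` is a path or an open text stream.  Header lines start with
    ``#`` and carry ``key: value`` metadata, which is preserved.  The
    delimiter is auto-detected among comma, tab and semicolon.  ``kind``
    always wins over any units declared in the header; a mismatch only
    produces a warning.
    """
    kind = Kind(kind)
    if isinstance(source, str):
        with open(source, "r", encoding="ascii") as fh:
            text = fh.read()
    else:
        text = source.read()

    metadata: dict[str, str] = {}
    wl: list[float] = []
    vals: list[float] = []
    delimiter: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            continue
        if delimiter is None:
            delimiter = _detect_delimiter(line)
        parts = [p for p in line.split(delimiter) if p.strip() != ""]
        if len(parts) < 2:
            raise SpdParseError(f"row {lineno}: expected two delimited columns, got {line!r}")
        try:
            w, v = float(parts[0]), float(parts[1])
        except ValueError:
            # allow a single non-numeric column-header row
            if not wl:
                continue
            raise SpdParseError(f"row {lineno}: non-numeric data in {line!r}") from None
        if wl and w <= wl[-1]:
            raise SpdParseError(
                f"row {lineno}: wavelength {w} nm not strictly increasing "
                f"(previous {wl[-1]} nm)"
            )
        wl.append(w)
        vals.append(v)

    if not wl:
        raise SpdParseError("no numeric data rows found")

    declared = metadata.get("units")
    if declared is None:
        warnings.warn(
            "no 'units' metadata in spectrum header; trusting the kind argument",
            stacklevel=2,
        )
    elif declared != kind.spectral_unit:
        warnings.warn(
            f"header declares units {declared!r} but kind argument implies "
            f"{kind.spectral_unit!r}; the kind argument wins",
            stacklevel=2,
        )

    return SpectralMeasurement(
        grid=WavelengthGrid.from_values(np.array(wl)),
        values=np.array(vals),
        kind=kind,
        label=metadata.get("label", ""),
        provenance=metadata.get("provenance", "measured"),
        metadata=metadata,
    )


def _format_number(x: float) -> str:
    # repr() gives the shortest decimal string that round-trips exactly,
    # always >= 6 significant digits for non-trivial values
    return repr(float(x))


def write_spd_tabulated(
    spd: SpectralMeasurement,
    spacing: float | None = None,
    stream: IO[str] | None = None,
) -> str:
    """Serialize an SPD to the uncompressed comma-separated exchange format.

    The export grid covers 380–780 nm at ``spacing`` nm (default: the input's
    native spacing clamped to the 1–10 nm tabulation range).  Samples outside
    the window are dropped with a warning; wavelengths the input does not
    cover are zero-filled.  Header lines record kind, units, label,
    provenance and any preserved metadata (instrument, timestamp, ...).
    """
    lo, hi = EXPORT_RANGE_NM
    if spacing is None:
        native = spd.grid.step if spd.grid.step is not None else 1.0
        spacing = float(min(max(native, EXPORT_SPACING_RANGE_NM[0]), EXPORT_SPACING_RANGE_NM[1]))
    if not (EXPORT_SPACING_RANGE_NM[0] <= spacing <= EXPORT_SPACING_RANGE_NM[1]):
        raise ValueError(
            f"tabulation spacing {spacing} nm outside the guideline range "
            f"{EXPORT_SPACING_RANGE_NM[0]:g}–{EXPORT_SPACING_RANGE_NM[1]:g} nm"
        )

    s_lo, s_hi = spd.grid.support
    if s_lo < lo - _UNIFORM_TOL_NM or s_hi > hi + _UNIFORM_TOL_NM:
        warnings.warn(
            f"input covers {s_lo:g}–{s_hi:g} nm; samples outside the "
            f"{lo:g}–{hi:g} nm export window are dropped",
            stacklevel=2,
        )

    target = WavelengthGrid.uniform(lo, hi, spacing)
    needs_resample = not (
        len(target) == len(spd.grid) and np.array_equal(target.values, spd.grid.values)
    )
    if needs_resample:
        out = resample(spd, target, _warn_outside=False)
    else:
        out = spd

    buf = io.StringIO()
    buf.write(f"# kind: {spd.kind.value}\n")
    buf.write(f"# units: {spd.kind.spectral_unit}\n")
    if spd.label:
        buf.write(f"# label: {spd.label}\n")
    buf.write(f"# provenance: {spd.provenance}\n")
    skip = {"kind", "units", "label", "provenance", "columns"}
    for key, value in spd.metadata.items():
        if key not in skip:
            buf.write(f"# {key}: {value}\n")
    buf.write("# columns: wavelength_nm,value\n")
    for w, v in zip(out.grid.values, out.values):
        buf.write(f"{_format_number(w)},{_format_number(v)}\n")

    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Resampling and scaling


def resample(
    spd: SpectralMeasurement,
    target: WavelengthGrid,
    *,
    _warn_outside: bool = True,
) -> SpectralMeasurement:
    """Piecewise-linear resampling onto ``target``; zero outside the support.

    Linear interpolation matches tabulated-data practice and keeps oracle
    testing exact; values are never extrapolated — wavelengths outside the
    input support are zero-filled with a warning (conservative for
    short-wavelength-weighted quantities).
    """
    s_lo, s_hi = spd.grid.support
    t_lo, t_hi = target.support
    if t_hi < s_lo or t_lo > s_hi:
        raise ValueError(
            f"target grid {t_lo:g}–{t_hi:g} nm does not overlap the "
            f"measurement support {s_lo:g}–{s_hi:g} nm"
        )
    outside = (target.values < s_lo - _UNIFORM_TOL_NM) | (
        target.values > s_hi + _UNIFORM_TOL_NM
    )
    if _warn_outside and np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} target wavelengths outside the measured support "
            f"{s_lo:g}–{s_hi:g} nm were zero-filled (no extrapolation)",
            stacklevel=2,
        )
    vals = np.interp(target.values, spd.grid.values, spd.values, left=0.0, right=0.0)
    return replace(spd, grid=target, values=vals)


def scale(spd: SpectralMeasurement, factor: float) -> SpectralMeasurement:
    """Multiply the spectrum pointwise; every derived scalar scales linearly."""
    if not np.isfinite(factor) or factor < 0:
        raise ValueError(f"scale factor must be finite and >= 0, got {factor}")
    return replace(spd, values=spd.values * float(factor))
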