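"""SPD container, ASCII round-trips, resampling and scaling."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculight import (
    Kind,
    SpectralMeasurement,
    WavelengthGrid,
    read_spd,
    resample,
    scale,
    standard_grid,
    write_spd_tabulated,
)
from oculight.spectral_core import SpdParseError


class TestWavelengthGrid:
    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WavelengthGrid(np.array([380.0, 390.0, 385.0]))

    def test_rejects_nonpositive_and_nonfinite(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([0.0, 10.0]))
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([380.0, np.nan]))

    def test_uniform_step_inferred(self):
        g = WavelengthGrid.from_values(np.arange(380.0, 781.0, 2.0))
        assert g.step == 2.0

    def test_declared_step_must_match(self):
        with pytest.raises(ValueError, match="uniform"):
            WavelengthGrid(np.array([380.0, 381.0, 383.0]), step=1.0)


class TestReadWrite:
    def test_constant_file_has_401_samples(self):
        rows = "# units: W/(m^2 nm)\n" + "\n".join(f"{w},0.001" for w in range(380, 781))
        spd = read_spd(io.StringIO(rows), Kind.IRRADIANCE)
        assert len(spd.grid) == 401
        assert np.all(spd.values == 0.001)

    def test_round_trip_preserves_grid_and_values(self, led_spd):
        text = write_spd_tabulated(led_spd)
        back = read_spd(io.StringIO(text), led_spd.kind)
        np.testing.assert_array_equal(back.grid.values, led_spd.grid.values)
        np.testing.assert_array_equal(back.values, led_spd.values)

    def test_export_read_export_is_byte_identical(self, led_spd):
        first = write_spd_tabulated(led_spd)
        second = write_spd_tabulated(read_spd(io.StringIO(first), led_spd.kind))
        assert first == second

    @pytest.mark.parametrize("delim", ["\t", ";"])
    def test_dialects_parse_identically(self, led_spd, delim):
        comma = write_spd_tabulated(led_spd)
        other = "# units: W/(m^2 nm)\n" + "\n".join(
            line.replace(",", delim)
            for line in comma.splitlines()
            if not line.startswith("#")
        )
        a = read_spd(io.StringIO(comma), Kind.IRRADIANCE)
        b = read_spd(io.StringIO(other), Kind.IRRADIANCE)
        np.testing.assert_array_equal(a.grid.values, b.grid.values)
        np.testing.assert_array_equal(a.values, b.values)

    def test_header_metadata_preserved(self):
        text = "# units: W/(m^2 nm)\n# instrument: SR-1000\n380,1.0\n381,2.0\n"
        spd = read_spd(io.StringIO(text), Kind.IRRADIANCE)
        assert spd.metadata["instrument"] == "SR-1000"

    def test_non_monotone_row_named_in_error(self):
        with pytest.raises(SpdParseError, match="row 3"):
            read_spd(io.StringIO("380,1\n390,1\n385,1\n"), Kind.IRRADIANCE)

    def test_missing_units_warns_and_kind_wins(self):
        with pytest.warns(UserWarning, match="units"):
            spd = read_spd(io.StringIO("380,1\n381,1\n"), Kind.RADIANCE)
        assert spd.kind is Kind.RADIANCE

    def test_export_covers_380_to_780(self, led_spd):
        rows = [
            line for line in write_spd_tabulated(led_spd, spacing=1.0).splitlines()
            if not line.startswith("#")
        ]
        assert rows[0].startswith("380.0,")
        assert rows[-1].startswith("780.0,")

    def test_spacing_outside_guideline_range_rejected(self, led_spd):
        for bad in (0.5, 11.0):
            with pytest.raises(ValueError, match="1–10 nm"):
                write_spd_tabulated(led_spd, spacing=bad)

    def test_out_of_window_samples_dropped_with_warning(self):
        grid = WavelengthGrid.uniform(300.0, 900.0, 5.0)
        spd = SpectralMeasurement(grid=grid, values=np.ones(len(grid)), kind=Kind.IRRADIANCE)
        with pytest.warns(UserWarning, match="dropped"):
            text = write_spd_tabulated(spd, spacing=5.0)
        wl = np.array([float(l.split(",")[0]) for l in text.splitlines() if not l.startswith("#")])
        assert wl.min() == 380.0 and wl.max() == 780.0


class TestResample:
    def test_identity_target(self, led_spd):
        out = resample(led_spd, led_spd.grid)
        np.testing.assert_array_equal(out.values, led_spd.values)

    def test_constant_spectrum_stays_constant(self):
        grid = WavelengthGrid.uniform(400.0, 700.0, 5.0)
        spd = SpectralMeasurement(grid=grid, values=np.full(len(grid), 3.5), kind=Kind.IRRADIANCE)
        out = resample(spd, WavelengthGrid.uniform(450.0, 650.0, 1.0))
        assert np.all(out.values == 3.5)

    def test_matches_brute_force_linear_oracle(self, coarse_spd):
        target = WavelengthGrid.uniform(380.0, 780.0, 1.0)
        out = resample(coarse_spd, target)
        xs, ys = coarse_spd.grid.values, coarse_spd.values
        oracle = np.empty(len(target))
        for i, w in enumerate(target.values):  # deliberate brute force
            if w in xs:
                oracle[i] = ys[np.where(xs == w)[0][0]]
            else:
                hi = int(np.searchsorted(xs, w))
                lo = hi - 1
                t = (w - xs[lo]) / (xs[hi] - xs[lo])
                oracle[i] = (1 - t) * ys[lo] + t * ys[hi]
        # the oracle's (1-t)*y0 + t*y1 form is algebraically identical but can
        # differ from the implementation by one rounding step
        assert np.max(np.abs(out.values - oracle)) <= 1e-15

    def test_zero_fill_outside_support_warns(self):
        grid = WavelengthGrid.uniform(500.0, 600.0, 1.0)
        spd = SpectralMeasurement(grid=grid, values=np.ones(len(grid)), kind=Kind.IRRADIANCE)
        with pytest.warns(UserWarning, match="zero-filled"):
            out = resample(spd, standard_grid())
        assert out.values[0] == 0.0 and out.values[-1] == 0.0

    def test_disjoint_support_is_error(self):
        grid = WavelengthGrid.uniform(500.0, 600.0, 1.0)
        spd = SpectralMeasurement(grid=grid, values=np.ones(len(grid)), kind=Kind.IRRADIANCE)
        with pytest.raises(ValueError, match="overlap"):
            resample(spd, WavelengthGrid.uniform(700.0, 750.0, 1.0))

    def test_windowing_and_resampling_commute(self, coarse_spd):
        fine = WavelengthGrid.uniform(380.0, 780.0, 1.0)
        window = WavelengthGrid.uniform(450.0, 650.0, 1.0)
        a = resample(resample(coarse_spd, fine), window)
        b = resample(coarse_spd, window)
        np.testing.assert_allclose(a.values, b.values, rtol=0, atol=1e-15)


class TestScale:
    def test_zero_and_identity(self, led_spd):
        assert np.all(scale(led_spd, 0.0).values == 0.0)
        np.testing.assert_array_equal(scale(led_spd, 1.0).values, led_spd.values)

    def test_negative_factor_rejected(self, led_spd):
        with pytest.raises(ValueError):
            scale(led_spd, -0.1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(factor=st.floats(0.0, 1e3, allow_nan=False))
    def test_pointwise_homogeneity(self, factor):
        grid = WavelengthGrid.uniform(400.0, 500.0, 10.0)
        spd = SpectralMeasurement(grid=grid, values=np.linspace(0, 1, len(grid)), kind=Kind.IRRADIANCE)
        np.testing.assert_allclose(scale(spd, factor).values, spd.values * factor, rtol=1e-15)


class TestNegativeValues:
    def test_flagged_and_clipped_on_request(self):
        grid = WavelengthGrid.uniform(380.0, 384.0, 1.0)
        spd = SpectralMeasurement(
            grid=grid, values=np.array([0.1, -0.01, 0.2, -0.005, 0.3]), kind=Kind.IRRADIANCE
        )
        assert spd.has_negative_values
        clipped = spd.clipped_nonnegative()
        assert not clipped.has_negative_values
        assert clipped.values[0] == 0.1 and clipped.values[1] == 0.0
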