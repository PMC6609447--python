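"""Alpha-opic panel, photometry, photon flux and the age sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculight import (
    ALPHA_OPIC_NAMES,
    Kind,
    SpectralMeasurement,
    age_sensitivity_analysis,
    alpha_opic_panel,
    photon_report,
    scale,
    weighted_integral,
)
from oculight.action_spectra import get_function
from oculight.quantities import (
    LUMINOUS_EFFICACY_LM_PER_W,
    PLANCK_H,
    SPEED_OF_LIGHT,
    panel_to_dict,
)
from oculight import fixtures


def fine_trapezoid_oracle(spd: SpectralMeasurement, name: str, step: float = 0.1) -> float:
    """Independent oracle: trapezoid rule at 0.1-nm oversampling."""
    a = get_function(name)
    lo = max(spd.grid.support[0], a.grid.support[0])
    hi = min(spd.grid.support[1], a.grid.support[1])
    wl = np.arange(lo, hi + step / 2, step)
    s = np.interp(wl, spd.grid.values, spd.values, left=0.0, right=0.0)
    w = np.interp(wl, a.grid.values, a.weights, left=0.0, right=0.0)
    return float(np.trapezoid(s * w, wl))


class TestWeightedIntegral:
    def test_zero_spectrum(self):
        spd = fixtures.monochromatic_spd(500.0, 0.0)
        assert weighted_integral(spd, get_function("melanopic")) == 0.0

    @pytest.mark.parametrize("name", ALPHA_OPIC_NAMES + ("photopic_V",))
    def test_unit_weight_at_peak_passes_band_power_through(self, name):
        from oculight import peak_wavelength

        a = get_function(name)
        spd = fixtures.monochromatic_spd(peak_wavelength(a), 1.0)
        assert weighted_integral(spd, a) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [11, 29, 47])
    def test_matches_fine_trapezoid_oracle(self, seed):
        spd = fixtures.random_gaussian_led_spd(seed)
        for name in ("melanopic", "photopic_V", "s_cone_opic"):
            ours = weighted_integral(spd, get_function(name))
            ref = fine_trapezoid_oracle(spd, name)
            assert ours == pytest.approx(ref, rel=1e-3)

    def test_disjoint_support_errors(self):
        from oculight import WavelengthGrid

        grid = WavelengthGrid.uniform(750.0, 780.0, 1.0)
        spd = SpectralMeasurement(grid=grid, values=np.ones(31), kind=Kind.RADIANCE)
        with pytest.raises(ValueError, match="overlap"):
            weighted_integral(spd, get_function("blue_light_hazard"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.0, 10.0, allow_nan=False),
        beta=st.floats(0.0, 10.0, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_linearity(self, alpha, beta, seed):
        x = fixtures.random_gaussian_led_spd(seed)
        y = fixtures.random_gaussian_led_spd(seed + 1)
        mel = get_function("melanopic")
        combo = SpectralMeasurement(
            grid=x.grid, values=alpha * x.values + beta * y.values, kind=x.kind
        )
        lhs = weighted_integral(combo, mel)
        rhs = alpha * weighted_integral(x, mel) + beta * weighted_integral(y, mel)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


class TestAlphaOpicPanel:
    def test_exactly_five_alpha_opic_entries_plus_photopic(self, led_spd):
        panel = alpha_opic_panel(led_spd)
        assert len(panel.alpha_opic_values()) == 5
        assert panel.photopic >= 0
        assert panel.photopic_unit == "lux"

    def test_555nm_monochromatic_gives_683_lux(self):
        spd = fixtures.monochromatic_spd(555.0, 1.0)
        assert alpha_opic_panel(spd).photopic == pytest.approx(683.0, rel=1e-12)

    def test_panel_scales_linearly(self, led_spd):
        p1 = alpha_opic_panel(led_spd)
        p2 = alpha_opic_panel(scale(led_spd, 2.0))
        for name in ALPHA_OPIC_NAMES:
            assert getattr(p2, name) == pytest.approx(2.0 * getattr(p1, name), rel=1e-12)
        assert p2.photopic == pytest.approx(2.0 * p1.photopic, rel=1e-12)

    def test_radiance_input_reports_luminance_units(self):
        spd = fixtures.planckian_spd(5000.0, 1e-6, kind=Kind.RADIANCE)
        panel = alpha_opic_panel(spd)
        assert panel.photopic_unit == "cd/m^2"
        assert panel.alpha_opic_unit == "mW/(m^2 sr)"

    def test_alpha_opic_values_in_milliwatts(self):
        # 1 W/m^2 at the melanopic peak -> 1000 mW/m^2 melanopic irradiance
        from oculight import peak_wavelength

        peak = peak_wavelength(get_function("melanopic"))
        panel = alpha_opic_panel(fixtures.monochromatic_spd(peak, 1.0))
        assert panel.melanopic == pytest.approx(1000.0, rel=1e-12)

    def test_metamers_share_illuminance_but_not_melanopic(self):
        a, b = fixtures.metamer_pair()
        pa, pb = alpha_opic_panel(a), alpha_opic_panel(b)
        assert pa.photopic == pytest.approx(pb.photopic, rel=1e-3)
        assert abs(pa.melanopic - pb.melanopic) / max(pa.melanopic, pb.melanopic) > 0.20


class TestPhotonReport:
    def test_zero_spectrum_total_zero_log_absent(self):
        report = photon_report(fixtures.monochromatic_spd(500.0, 0.0))
        assert report.total_photon_irradiance == 0.0
        assert report.log10_total is None

    def test_500nm_single_bin_against_hc_over_lambda(self):
        report = photon_report(fixtures.monochromatic_spd(500.0, 1.0))
        expected = 1.0 * 500e-9 / (PLANCK_H * SPEED_OF_LIGHT) * 1e-4
        assert report.total_photon_irradiance == pytest.approx(expected, rel=1e-6)
        assert report.total_photon_irradiance == pytest.approx(2.517e14, rel=1e-3)
        assert report.log10_total == pytest.approx(np.log10(expected), rel=1e-9)

    def test_doubling_wavelength_doubles_photon_rate(self):
        lo = photon_report(fixtures.monochromatic_spd(380.0, 1.0))
        hi = photon_report(fixtures.monochromatic_spd(760.0, 1.0))
        assert hi.total_photon_irradiance == pytest.approx(
            2.0 * lo.total_photon_irradiance, rel=1e-12
        )

    def test_radiance_input_rejected(self):
        spd = fixtures.planckian_spd(5000.0, 1.0, kind=Kind.RADIANCE)
        with pytest.raises(ValueError, match="irradiance"):
            photon_report(spd)


class TestAgeSensitivity:
    def test_single_standard_age_matches_plain_panel(self, led_spd):
        table = age_sensitivity_analysis(led_spd, [32.0])
        plain = panel_to_dict(alpha_opic_panel(led_spd))
        row = table.loc[32.0]
        for key, value in plain.items():
            if isinstance(value, float) and key in row:
                assert row[key] == pytest.approx(value, rel=1e-12)

    def test_melanopic_monotone_non_increasing_with_age(self):
        blue = fixtures.gaussian_led_spd([(480.0, 20.0, 1.0)])
        table = age_sensitivity_analysis(blue, [32, 40, 50, 60, 70])
        mel = table["melanopic_mW_per_m2"].to_numpy()
        assert np.all(np.diff(mel) <= 0)
        assert mel[-1] < mel[0]

    def test_zero_spectrum_all_rows_zero(self):
        table = age_sensitivity_analysis(fixtures.monochromatic_spd(500.0, 0.0), [32, 50, 70])
        numeric = table.select_dtypes("number")
        assert (numeric.to_numpy() == 0).all()

    def test_empty_age_list_errors(self, led_spd):
        with pytest.raises(ValueError, match="empty"):
            age_sensitivity_analysis(led_spd, [])
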