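import numpy as np
import pytest

from oculight import Kind, SpectralMeasurement, WavelengthGrid
from oculight import fixtures


@pytest.fixture
def led_spd() -> SpectralMeasurement:
    """A three-primary LED mixture (irradiance), the workhorse fixture."""
    return fixtures.gaussian_led_spd(
        [(455.0, 18.0, 0.25), (520.0, 30.0, 0.45), (630.0, 20.0, 0.30)]
    )


@pytest.fixture
def coarse_spd() -> SpectralMeasurement:
    """A smooth spectrum tabulated at 5 nm, for resampling tests."""
    grid = WavelengthGrid.uniform(380.0, 780.0, 5.0)
    values = 1.0 + np.sin(grid.values / 40.0) ** 2
    return SpectralMeasurement(grid=grid, values=values, kind=Kind.IRRADIANCE)


@pytest.fixture
def complete_record(tmp_path):
    return fixtures.complete_record(tmp_path)
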