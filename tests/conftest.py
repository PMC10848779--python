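import numpy as np
import pytest

from cpdrepair.spectra import (
    EMISSION_DENSITY,
    MOLAR_ABSORPTION,
    Beam,
    SampleCell,
    Spectrum,
    gaussian_emission,
)


@pytest.fixture
def cell():
    return SampleCell(path_length_cm=1.0, volume_L=200e-6)


@pytest.fixture
def led_beam():
    """The irradiation source: 285 nm center, 15 nm FWHM, 0.36 mW."""
    return Beam(gaussian_emission(285.0, 15.0), 0.36e-3)


@pytest.fixture
def narrow_beam():
    """Quasi-monochromatic 285 nm line (0.05 nm FWHM) for closed-form checks."""
    grid = np.arange(284.0, 286.005, 0.01)
    return Beam(gaussian_emission(285.0, 0.05, grid), 0.36e-3)


def flat_epsilon(value, grid=None):
    grid = np.arange(220.0, 341.0, 1.0) if grid is None else np.asarray(grid, float)
    return Spectrum(grid, np.full(grid.size, float(value)), MOLAR_ABSORPTION)
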