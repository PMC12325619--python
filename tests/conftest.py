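import numpy as np
import pytest

from uvresolve import (
    DEFAULT_GRID,
    ETHANOL,
    absorptivity_spectrum,
    preset_hctz,
    preset_trim,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def hctz_model():
    return preset_hctz()


@pytest.fixture(scope="session")
def trim_model():
    return preset_trim()


@pytest.fixture(scope="session")
def hctz_unit(hctz_model, grid):
    """Noiseless unit-concentration HCTZ spectrum on the default grid."""
    return absorptivity_spectrum(hctz_model, ETHANOL, grid)


@pytest.fixture(scope="session")
def trim_unit(trim_model, grid):
    """Noiseless unit-concentration TRIM spectrum on the default grid."""
    return absorptivity_spectrum(trim_model, ETHANOL, grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
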