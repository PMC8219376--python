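import numpy as np
import pytest

from qpisim.optics import Field, GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_grid():
    """64-pixel grid at 5 um pitch, HeNe wavelength."""
    return GridSpec(64, 5e-6, 632.8e-9)


@pytest.fixture
def random_field(small_grid, rng):
    values = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
    return Field(small_grid, values)


def matched_grid(n: int, focal_length: float, wavelength: float = 632.8e-9) -> GridSpec:
    """Grid whose Fourier-plane pitch equals its own pitch for this lens."""
    return GridSpec(n, float(np.sqrt(wavelength * focal_length / n)), wavelength)
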