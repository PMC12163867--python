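import numpy as np
import pytest

from flimphasor import DecayCube, SyntheticSpec
from flimphasor.synthetic import generate_cube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basic_spec():
    """80 MHz, 256 bins spanning one 12.5 ns period, noiseless 4 ns dye."""
    return SyntheticSpec(
        shape=(8, 8),
        n_bins=256,
        rep_frequency=80.0,
        components=[(4.0, 1.0)],
        photons_per_pixel=1000.0,
    )


@pytest.fixture
def basic_cube(basic_spec):
    cube, _ = generate_cube(basic_spec)
    return cube


@pytest.fixture
def random_int_cube(rng):
    """Small integer cube with a valid 80 MHz timing block."""
    counts = rng.integers(0, 300, size=(6, 5, 64)).astype(np.uint32)
    return DecayCube(
        counts=counts, bin_width=12.5 / 64, rep_frequency=80.0, source_path="<test>"
    )
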