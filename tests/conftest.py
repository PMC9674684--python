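import numpy as np
import pytest

from qsplit import build_axis
from qsplit.fixtures import make_doublet_spectrum

#: splittings resembling the five-leucine labelling pattern, Hz
FIVE_SPLITTINGS = (12_000.0, 18_000.0, 25_000.0, 33_000.0, 41_000.0)


@pytest.fixture(scope="session")
def instrument_axis():
    """Acquisition axis of the oriented-sample experiments: 32 k points,
    43.1 kHz width."""
    return build_axis(32768, 43_100.0)


@pytest.fixture(scope="session")
def five_doublet_spectrum(instrument_axis):
    spec, truth = make_doublet_spectrum(FIVE_SPLITTINGS, axis=instrument_axis,
                                        noise_sd=0.01, seed=11)
    return spec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
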