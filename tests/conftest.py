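import numpy as np
import pytest

from phycovoc.quantify import KineticsParams, StrippingParams
from phycovoc.synthetic import (
    ExperimentDesign,
    InstrumentParams,
    make_compound_library,
)


@pytest.fixture(scope="session")
def anchor_library():
    """The nine fixed anchor compounds only."""
    return make_compound_library(9, 4, seed=0)


@pytest.fixture(scope="session")
def full_library():
    """A full 72-signal library at a fixed seed."""
    return make_compound_library(72, 40, seed=11)


@pytest.fixture(scope="session")
def clean_instrument():
    """Noise-free, drift-free instrument for closure checks."""
    return InstrumentParams(noise_sd=0.0, mass_drift=(1.0, 0.0))


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign(seed=7)


@pytest.fixture(scope="session")
def stripping():
    return StrippingParams()


@pytest.fixture(scope="session")
def kinetics():
    return KineticsParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
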