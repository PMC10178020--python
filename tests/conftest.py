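import numpy as np
import pytest

from glycodec import Config
from glycodec.simulator import CLEAN_PARAMS, SimParams, simulate_glycopeptide


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def clean_glyco():
    """A noise-free, fully covered glycopeptide spectrum with its truth."""
    return simulate_glycopeptide(
        "EEQFNSTFR",
        {"Hex": 5, "HexNAc": 4, "NeuAc": 2},
        2,
        CLEAN_PARAMS,
        np.random.default_rng(7),
        identifier="clean_glyco",
    )


@pytest.fixture
def noisy_params():
    return SimParams(seed=123)
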