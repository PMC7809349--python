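import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mwimap.epg import EchoTrainSpec, T2Grid
from mwimap.phantom import make_phantom
from mwimap.reference import (brain_steady_state_protocol,
                              cord_grase_protocol,
                              cord_steady_state_protocol)


@pytest.fixture(scope="session")
def cord_spec() -> EchoTrainSpec:
    return cord_grase_protocol()


@pytest.fixture(scope="session")
def grid() -> T2Grid:
    return T2Grid()


@pytest.fixture(scope="session")
def brain_protocol():
    return brain_steady_state_protocol()


@pytest.fixture(scope="session")
def cord_protocol():
    return cord_steady_state_protocol()


@pytest.fixture(scope="session")
def brain_truth():
    truth, labels = make_phantom("brain", (16, 16, 16), seed=1)
    return truth


@pytest.fixture(scope="session")
def cord_truth():
    truth, labels = make_phantom("cord", (32, 32, 8), seed=1)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
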