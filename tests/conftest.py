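import warnings

import numpy as np
import pytest

from mobiphys.design import DesignSpec, scaled_design
from mobiphys import synth

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def short_design() -> DesignSpec:
    """A 1/8-scale design so sessions stay small in unit tests."""
    return scaled_design(0.125)


@pytest.fixture(scope="session")
def short_session(short_design):
    """A small complete walking-group session plus its ground truth."""
    return synth.generate_session(short_design, "walking", seed=42,
                                  participant="P01")


@pytest.fixture(scope="session")
def short_standing_session(short_design):
    return synth.generate_session(short_design, "standing", seed=43,
                                  participant="P02")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
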