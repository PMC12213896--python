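import numpy as np
import pytest

from thermorad.model_core import ModelParams
from thermorad.workbench import fixtures as representative_fixtures


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def representatives() -> dict:
    """The six representative tumours A1-C1 (NL) and A2-C2 (SL)."""
    return representative_fixtures()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
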