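import numpy as np
import pytest

from topoburst.thermo import ThermoParams


@pytest.fixture(scope="session")
def thermo_params() -> ThermoParams:
    """Default published parameter set (180-bp ring, 8-bp promoter, 298.15 K)."""
    return ThermoParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160206)
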