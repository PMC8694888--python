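import numpy as np
import pytest

from microemu.potential import PotentialParams, tabulate


@pytest.fixture(scope="session")
def default_params():
    return PotentialParams()


@pytest.fixture(scope="session")
def params_np4():
    return PotentialParams(N_p=4)


@pytest.fixture(scope="session")
def pot_np0():
    return tabulate(PotentialParams(N_p=0))


@pytest.fixture(scope="session")
def pot_np4():
    return tabulate(PotentialParams(N_p=4))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
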