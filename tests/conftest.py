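import numpy as np
import pytest

from germscreen.presets import get_exposure, get_strain, vehicle_exposure


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def screen_strain():
    return get_strain("screen")


@pytest.fixture
def him8_strain():
    return get_strain("him-8")


@pytest.fixture
def vehicle():
    return vehicle_exposure()


@pytest.fixture
def dbp():
    return get_exposure("DBP")
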