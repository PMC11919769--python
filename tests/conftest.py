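import numpy as np
import pytest

import photopore as pp

UV = pp.LightField.single(365, 36.2)
GREEN = pp.LightField.single(530, 30.3)
BLUE = pp.LightField.single(455, 56.3)


@pytest.fixture(scope="session")
def pzme():
    return pp.preset("pzMe")


@pytest.fixture(scope="session")
def cond():
    return pp.ConductanceModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
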