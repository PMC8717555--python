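import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "silksim",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("silksim")


@pytest.fixture(scope="session")
def unit_cell():
    from silksim.builder import build_unit_cell
    return build_unit_cell()


@pytest.fixture(scope="session")
def supercell_2x2x2(unit_cell):
    from silksim.builder import replicate
    return replicate(unit_cell, 2, 2, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
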