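import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def interface_curves():
    """SPR curves of the cell and background stacks on the standard sweep."""
    from plasmonet import optics

    cell, bg = optics.build_interface_stacks()
    return optics.spr_curve(cell), optics.spr_curve(bg)
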