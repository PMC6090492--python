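import numpy as np
import pytest

from constructsim import MaterialModel, build_mesh


@pytest.fixture
def material():
    return MaterialModel()


@pytest.fixture
def unit_element():
    """Single 1-mm cube element."""
    return build_mesh((0.001, 0.001, 0.001), 0.001)


@pytest.fixture
def bar_mesh():
    """10 x 1 x 1 element bar, 1-mm cubes."""
    return build_mesh((0.010, 0.001, 0.001), 0.001)


@pytest.fixture
def construct_mesh():
    """Full-size reference construct at the default 1-mm discretisation."""
    return build_mesh((0.030, 0.020, 0.012), 0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
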