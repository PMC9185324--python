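import numpy as np
import pytest

from brushwear.geometry import MotionProfile, build_brush, build_teeth


@pytest.fixture(scope="session")
def assembly():
    return build_brush()


@pytest.fixture(scope="session")
def teeth():
    return build_teeth()


@pytest.fixture()
def motion():
    return MotionProfile(speed=0.1, depth=0.9e-3, stroke=56.0e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
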