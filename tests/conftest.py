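import numpy as np
import pytest

from echostruct.imaging_io import EchoFrame, RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_frame():
    def make(value: int, shape=(64, 64)) -> EchoFrame:
        return EchoFrame(pixels=np.full(shape, value, dtype=np.uint8), source_id="const")

    return make


@pytest.fixture
def random_frame(rng):
    return EchoFrame(pixels=rng.integers(0, 256, size=(64, 64), dtype=np.uint8).astype(np.uint8))


@pytest.fixture
def rect_roi():
    def make(r0, c0, r1, c1, label="pericardial") -> RegionOfInterest:
        return RegionOfInterest(label=label, vertices=[(r0, c0), (r0, c1), (r1, c1), (r1, c0)])

    return make
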