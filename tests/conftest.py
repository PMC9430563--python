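import numpy as np
import pytest

from agardrift import Calibration, ChannelMeta, HyperStack


@pytest.fixture
def cal():
    """Typical acquisition calibration: 1 μm pixels, 2 μm slices, 30 min frames."""
    return Calibration(pixel_size_xy=1.0, z_step=2.0, time_interval=30.0)


@pytest.fixture
def random_stack_factory(cal):
    """Build a random uint8/uint16 stack of given dims from a seeded RNG."""

    def make(dims=(3, 2, 8, 12, 12), dtype=np.uint8, seed=0, calibration=None):
        rng = np.random.default_rng(seed)
        hi = 256 if dtype == np.uint8 else 65536
        pix = rng.integers(0, hi, dims, dtype=dtype)
        channels = [
            ChannelMeta(name=f"ch{i}", color=((37 * i) % 256, (91 * i) % 256, 255 - (13 * i) % 256))
            for i in range(dims[1])
        ]
        return HyperStack.from_array(pix, calibration or cal, channels)

    return make
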