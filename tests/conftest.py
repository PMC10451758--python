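import numpy as np
import pytest

from sdstrack.geometry import CameraIntrinsics
from sdstrack.rgbd_io import RGBDFrame, SequenceMeta


@pytest.fixture
def intrinsics():
    return CameraIntrinsics(fx=300.0, fy=300.0, cx=127.5, cy=127.5)


@pytest.fixture
def meta(intrinsics):
    return SequenceMeta(fps=30.0, width=64, height=64, intrinsics=intrinsics,
                        subject_id="test", depth_unit_scale=1.0)


def make_random_frame(rng, height=64, width=64, index=0):
    color = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    depth = rng.integers(0, 1000, size=(height, width)).astype(np.float32)
    return RGBDFrame(color=color, depth=depth, index=index,
                     timestamp=index / 30.0)


@pytest.fixture
def random_frames():
    rng = np.random.default_rng(42)
    return [make_random_frame(rng, index=i) for i in range(3)]
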