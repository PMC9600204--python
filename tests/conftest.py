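import numpy as np
import pytest

import hbscreen as hb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_strip():
    """One default-condition strip with its ground truth."""
    return hb.render_strip(hb.StripSpec(seed=5))


@pytest.fixture(scope="session")
def clean_lanes():
    """120 well-separated, low-noise lanes for fast classifier tests."""
    lanes = []
    for s in range(15):
        strip, gt = hb.render_strip(
            hb.clean_strip_spec(seed=4000 + s),
            population=hb.WELL_SEPARATED_POPULATION,
        )
        for box, label in zip(gt.lane_boxes, gt.labels):
            lane = hb.crop_and_resize(strip, box)
            lane.label = label
            lanes.append(lane)
    return lanes


def make_uniform_lane(r=200, g=180, b=190, label=None):
    px = np.zeros((*hb.LANE_SHAPE, 3), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = r, g, b
    return hb.LaneImage(pixels=px, label=label)


@pytest.fixture
def uniform_lane():
    return make_uniform_lane()
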