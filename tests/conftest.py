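from datetime import datetime, timedelta

import numpy as np
import pytest

from leaftrack.render import disc_coverage
from leaftrack.tracking import Frame

BG = 0.06
FG = 0.85
BEAD_RADIUS_PX = 21.0   # 20 mm diameter at 2.1 px/mm


def render_disc_frame(center_xy, shape=(160, 160), radius=BEAD_RADIUS_PX,
                      noise_sd=0.0, rng=None, timestamp=None, index=0):
    """Small single-bead frame rendered by exact pixel coverage."""
    img = BG + (FG - BG) * disc_coverage(shape, center_xy, radius)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    ts = timestamp or datetime(2014, 4, 22, 10, 0, 0)
    return Frame(pixels=img, timestamp=ts, index=index)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def disc_frame():
    return render_disc_frame((80.0, 80.0))


def make_sequence(centers, shape=(160, 160), noise_sd=0.0, seed=0,
                  start=None, dt_s=120.0):
    """Frames with one bead at the given per-frame centers."""
    rng = np.random.default_rng(seed)
    start = start or datetime(2014, 4, 22, 10, 0, 0)
    return [
        render_disc_frame(c, shape=shape, noise_sd=noise_sd, rng=rng,
                          timestamp=start + timedelta(seconds=k * dt_s),
                          index=k)
        for k, c in enumerate(centers)
    ]
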