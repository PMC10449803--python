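import numpy as np
import pytest

import neomotion as nm
from neomotion import motion as mot


@pytest.fixture(scope="session")
def small_video():
    """A 30 s quarter-scale recording with known limb rhythms.

    Upper limbs wiggle at 0.6 Hz, lower limbs at 1.2 Hz; returned with
    its ground-truth record.
    """
    scn = nm.default_video_scenario(
        duration_s=30.0, width=240, height=160, seed=7,
        lower_freq_hz=1.2, upper_freq_hz=0.6,
    )
    seq, truth = nm.generate_video(scn)
    return scn, seq, truth


@pytest.fixture(scope="session")
def small_video_motion(small_video):
    """Background, regions and motion series extracted from small_video."""
    _, seq, _ = small_video
    background = mot.estimate_background(seq)
    ref = mot.reference_silhouette(seq, background)
    regions = mot.build_regions(ref)
    ts = mot.motion_series(seq, regions)
    return background, regions, ts


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
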