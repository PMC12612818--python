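import numpy as np
import pytest

from trichotrack.config import Calibration, SegmentationParams, SimulationConfig
from trichotrack.simulate import simulate_movie


@pytest.fixture(scope="session")
def cal():
    return Calibration(pixel_size_um=1.8, frame_interval_s=0.45)


@pytest.fixture(scope="session")
def seg_params():
    # published defaults plus a fallback threshold so that cell-free frames
    # (whose histograms never turn bimodal) segment to "nothing"
    return SegmentationParams(fallback_threshold=255)


@pytest.fixture(scope="session")
def small_movie():
    """Small mixed co-culture scene used by several modules' tests."""
    cfg = SimulationConfig(field_width_px=256, field_height_px=256, n_frames=15,
                           frame_interval_s=0.45, n_flagellates=10, n_bacteria=30,
                           flagellate_speed_dist=(10.2, 0.35), seed=42)
    return simulate_movie(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
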