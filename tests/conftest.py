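import numpy as np
import pytest

from thermoface import EventDesign, FacePhantomConfig, ResponseConfig
from thermoface.landmarks import N_LANDMARKS, LandmarkFrame
from thermoface.synthetic import canonical_landmarks


@pytest.fixture
def design():
    """The standard single-event design: onset 40 s, 5 s pre / 10 s post."""
    return EventDesign()


@pytest.fixture
def half_phantom():
    """320x240 phantom (half scale): cheap to render, same structure."""
    return FacePhantomConfig(dims=(320, 240))


@pytest.fixture
def quiet_half_phantom():
    """Half-scale phantom with no motion and no sensor noise."""
    return FacePhantomConfig(dims=(320, 240), sensor_noise_sd_C=0.0,
                             motion_walk_sd_px=0.0, motion_drift_amp_px=0.0)


def make_truth_sequence(n_frames: int, dims=(320, 240), walk_sd=0.3, seed=0):
    """Rigidly moving truth landmark trajectory, no video rendering."""
    rng = np.random.default_rng(seed)
    tpl = canonical_landmarks(dims)
    shifts = np.cumsum(rng.normal(0, walk_sd, size=(n_frames, 2)), axis=0)
    return [LandmarkFrame(k, tpl + shifts[k], np.ones(N_LANDMARKS), source="truth")
            for k in range(n_frames)]


@pytest.fixture
def truth_sequence():
    return make_truth_sequence(50)
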