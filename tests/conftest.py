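import numpy as np
import pytest

from oculaff.recordings import RawRecording
from oculaff.simulate import class_profile, generate_recording


@pytest.fixture
def simple_recording():
    """2 s of gaze at screen center at 240 Hz, clean confidence."""
    n = 481
    t = np.arange(n) / 240.0
    return RawRecording(
        participant_id="p01", video_id="v01", fs_hz=240.0, t=t,
        gaze_x=np.full(n, 0.5), gaze_y=np.full(n, 0.5),
        pupil_mm=np.full(n, 3.8), confidence=np.ones(n),
        clip_duration_s=2.0)


@pytest.fixture(scope="session")
def ha_recording():
    """One 60 s synthetic high-arousal recording with ground truth."""
    return generate_recording(class_profile("HA"), duration_s=60.0, seed=123)


@pytest.fixture(scope="session")
def noiseless_recording():
    """Noise-free synthetic recording for exact event recovery checks."""
    return generate_recording(class_profile("LA"), duration_s=30.0, seed=7,
                              noiseless=True)
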