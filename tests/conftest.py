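import numpy as np
import pytest

from imuagree.io import Activity, Device, Location, SensorRecording
from imuagree.signal_prep import euler_zxy_to_quat


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(rng):
    """A small, fully random but valid squat recording."""
    n = 240
    z = 10 * np.sin(np.linspace(0, 4 * np.pi, n))
    x = 20 * np.cos(np.linspace(0, 4 * np.pi, n)) - 5
    y = 5 * np.sin(np.linspace(0, 2 * np.pi, n))
    quat = euler_zxy_to_quat(z, x, y)
    acc = rng.normal(0, 2, size=(n, 3))
    return SensorRecording(
        participant_id="P01",
        device=Device.TEST,
        location=Location.THIGH,
        session=1,
        activity=Activity.SQUAT,
        quat=quat,
        free_acc=acc,
    )
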