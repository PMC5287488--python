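import numpy as np
import pandas as pd
import pytest

from wristpa.config import PipelineConfig
from wristpa.raw_io import RawRecording


@pytest.fixture
def config():
    """Full-fidelity configuration (100 Hz, 20 Hz cutoff)."""
    return PipelineConfig()


@pytest.fixture
def config25():
    """Scaled configuration for fast tests: 25 Hz grid with the filter
    cutoff scaled proportionally (20/100 of the rate)."""
    return PipelineConfig(resample_rate_hz=25, filter_cutoff_hz=5)


@pytest.fixture
def config10():
    """Heavily scaled configuration for cohort-sized tests."""
    return PipelineConfig(resample_rate_hz=10, filter_cutoff_hz=2)


def make_recording(xyz, rate_hz=100.0, start="2014-05-12T10:00:00+01:00",
                   device_id="dev001", temperature_c=None):
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    return RawRecording(
        device_id=device_id,
        start_time=pd.Timestamp(start),
        nominal_rate_hz=rate_hz,
        t=np.arange(n) / rate_hz,
        xyz=xyz,
        temperature_c=temperature_c,
    )


@pytest.fixture
def still_recording():
    """30 s of exactly constant (0, 0, 1) g at 100 Hz."""
    return make_recording(np.tile([0.0, 0.0, 1.0], (3000, 1)))
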