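import numpy as np
import pytest

from eyebci import DetectorConfig, SessionSpec, design_bandpass, generate_session


@pytest.fixture(scope="session")
def bandpass():
    return design_bandpass()


@pytest.fixture()
def config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def mixed_session():
    """A 60 s labeled session with blinks and both lateral directions.

    Events are spaced 2.5 s apart: the detector's accumulation windows can
    span up to ~1.6 s, and in the intended use the operator pauses between
    commands.
    """
    spec = SessionSpec(
        duration_s=60.0,
        seed=11,
        counts={"blink": 10, "look_left": 5, "look_right": 5},
        min_separation_s=2.5,
    )
    return generate_session(spec)


@pytest.fixture(scope="session")
def background_session():
    """Pure background (no events) for false-alarm checks."""
    return generate_session(SessionSpec(duration_s=60.0, seed=23))


def make_recording(data, fs=500.0, channels=("Fp1", "F7", "F8")):
    from eyebci import Recording

    data = np.asarray(data, dtype=float)
    return Recording(fs=fs, channels=channels, data=data)
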