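import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

from mousedisco import AudioFixtureSpec, AudioSignal, gen_audio


@pytest.fixture(scope="session")
def tone_1k():
    """5 s pure 1 kHz tone at 44.1 kHz."""
    return gen_audio(AudioFixtureSpec("tone", 5.0, 44_100.0, 0, {"frequency": 1000.0}))


@pytest.fixture(scope="session")
def white_noise():
    """5 s unit white noise at 22.05 kHz."""
    rng = np.random.default_rng(11)
    x = rng.standard_normal(int(5 * 22_050))
    return AudioSignal(x / np.max(np.abs(x)), 22_050.0)


@pytest.fixture(scope="session")
def click_120bpm():
    """30 s jitter-free click train at 120 BPM."""
    return gen_audio(
        AudioFixtureSpec("click_train", 30.0, 22_050.0, 3, {"bpm": 120.0})
    )
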