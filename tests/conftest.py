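import numpy as np
import pytest

from peepkit.dsp import AudioRecording
from peepkit.synth import PopulationSpec


FS = 44100.0


def tone(freq: float, duration: float, fs: float = FS, amp: float = 0.5,
         envelope=None) -> np.ndarray:
    t = (np.arange(int(round(duration * fs))) + 0.5) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    if envelope is not None:
        x = x * envelope(t)
    return x


@pytest.fixture
def tone_rec() -> AudioRecording:
    """One second of a pure 6,724 Hz tone."""
    return AudioRecording(tone(6724.0, 1.0), FS, recording_id="tone")


@pytest.fixture
def small_spec() -> PopulationSpec:
    return PopulationSpec(n_males=4, seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
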