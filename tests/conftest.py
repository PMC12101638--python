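import numpy as np
import pytest

from avfsound import segmentation, synthetic
from avfsound.audio import AudioRecording


@pytest.fixture(scope="session")
def healthy_profile() -> synthetic.SubjectProfile:
    """A subject with no risk history: no diabetes, no hypertension,
    no AVF-related event, fistula under five years old."""
    return synthetic.SubjectProfile("S001", dm=0, ht=0, event=0, vintage_years=2.0)


@pytest.fixture(scope="session")
def bruit_recording(healthy_profile) -> AudioRecording:
    """A default synthetic bruit: 15 cycles of ~0.8 s with the power
    peak at 20% of each cycle."""
    return synthetic.generate_waveform(
        healthy_profile, synthetic.AcousticsConfig(tmp_target=20.0, seed=11))


@pytest.fixture(scope="session")
def bruit_cycles(bruit_recording):
    """Detected cycles of the default synthetic bruit."""
    env = segmentation.compute_envelope(bruit_recording)
    return segmentation.detect_cycles(env, bruit_recording.sample_rate)


def make_tone(freq_hz: float, duration: float = 1.0, sample_rate: int = 8000,
              amplitude: float = 0.5) -> np.ndarray:
    t = np.arange(int(duration * sample_rate)) / sample_rate
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
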