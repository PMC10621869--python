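import numpy as np
import pytest

from wemd_apnea.multirate import design_lowpass_fir
from wemd_apnea.synthetic import SyntheticConfig, generate_ecg


@pytest.fixture(scope="session")
def default_fir():
    return design_lowpass_fir()


@pytest.fixture(scope="session")
def clean_segment():
    """A noise-free 60-s, 100 Hz segment at 60 bpm."""
    cfg = SyntheticConfig(seed=7, noise_sd=0.0)
    return generate_ecg(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def detect_beats(samples: np.ndarray, fs: float) -> np.ndarray:
    """Independent threshold peak detector used as an oracle for beat timing."""
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(samples, height=0.5, distance=int(0.3 * fs))
    return peaks / fs
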