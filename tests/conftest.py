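import numpy as np
import pytest

from bcifes.montage import Montage, default_montage
from bcifes.recording import Recording
from bcifes.simulate_eeg import BandComponent, EEGSimConfig


@pytest.fixture
def montage() -> Montage:
    return default_montage()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def tone_config(
    channel: str = "C3",
    freq: float = 10.0,
    rms: float = 10.0,
    duration: float = 120.0,
    bandwidth: float = 0.0,
) -> EEGSimConfig:
    """Noise-free single-oscillator configuration on the full montage."""
    return EEGSimConfig(
        duration=duration,
        band_components=(BandComponent(channel, freq, bandwidth, rms),),
        background_rms=0.0,
        line_noise_amplitude=0.0,
        ocular_artifact_rate=0.0,
    )


def make_recording(
    data: np.ndarray,
    sampling_rate: float = 250.0,
    montage: Montage | None = None,
    **kwargs,
) -> Recording:
    montage = montage or default_montage()
    return Recording(samples=data, sampling_rate=sampling_rate,
                     montage=montage, **kwargs)


@pytest.fixture
def clean_session(montage):
    """Two noise-free 5-min recordings that survive preprocessing intact."""
    from bcifes.simulate_eeg import generate_recording

    cfg = EEGSimConfig(
        duration=300.0,
        band_components=(
            BandComponent("C3", 10.0, 2.0, 5.0),
            BandComponent("C4", 10.0, 2.0, 5.0),
            BandComponent("Cz", 6.0, 2.0, 4.0),
        ),
        background_rms=2.0,
        line_noise_amplitude=0.0,
        ocular_artifact_rate=0.0,
    )
    return [
        generate_recording(cfg, seed=11, recording_index=1),
        generate_recording(cfg, seed=12, recording_index=2),
    ]
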