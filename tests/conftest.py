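import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuroloop import SessionConfig, SynthConfig, generate_recording

settings.register_profile(
    "default",
    settings(
        max_examples=50,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture
def small_cfg():
    """Two quiet channels at 16 kHz with the demo-style detection window."""
    return SessionConfig(
        sampling_rate_hz=16000,
        n_channels=2,
        block_samples=64,
        waveform_pre_ms=1.0,
        waveform_post_ms=7.0,
        threshold_volts=-30e-6,
    )


@pytest.fixture
def noisy_recording():
    """Short 2-channel recording with background spiking and noise."""
    cfg = SynthConfig(
        duration_s=3.072,  # 49152 samples: a multiple of every tested block size
        n_channels=2,
        sampling_rate_hz=16000,
        noise_sd=8e-6,
        background_rate_hz=5.0,
        seed=7,
    )
    return generate_recording(cfg)
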