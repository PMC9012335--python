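import warnings

import numpy as np
import pytest

from uemg.core import Phase, Segment
from uemg.synth import GeneratorConfig


@pytest.fixture(autouse=True)
def _silence_rate_flag():
    # the default LP preset sits below the physiological rate band by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="contraction_rate .* outside", category=UserWarning)
        yield


def make_tone_segment(
    freq: float,
    amplitude: float = 1.0,
    fs: float = 32.0,
    duration: float = 300.0,
    phase_rad: float = 0.0,
    **seg_kwargs,
) -> Segment:
    t = np.arange(int(round(duration * fs))) / fs
    return Segment(
        samples=amplitude * np.cos(2 * np.pi * freq * t + phase_rad),
        sampling_rate=fs,
        **seg_kwargs,
    )


@pytest.fixture
def tone_segment():
    return make_tone_segment


@pytest.fixture
def clean_config():
    """Noise-, drift- and artifact-free generator config (pure slow wave)."""

    def _make(**overrides) -> GeneratorConfig:
        base = dict(
            phase=Phase.PP,
            contraction_rate=2.4,
            slow_wave_amplitude=100.0,
            modulation_depth=0.0,
            spike_burst_amplitude=0.0,
            drift_amplitude=0.0,
            noise_sd=0.0,
            mains_amplitude=0.0,
            cardiac_amplitude=0.0,
            respiration_amplitude=0.0,
            duration=300.0,
            n_channels=1,
            seed=0,
        )
        base.update(overrides)
        return GeneratorConfig(**base)

    return _make
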