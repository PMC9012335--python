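"""Synthetic uterine-EMG generator.

Produces multichannel recordings whose first channel carries a quasi-periodic
contraction slow wave plus the nuisance components a real intrauterine
recording would contain: spike bursts gated by the slow wave, baseline drift,
mains/cardiac/respiration tones and white noise. Phase presets encode the
expected proliferative (PP: faster rhythm, lower amplitude) versus luteal
(LP: slower rhythm, higher amplitude) contrast so that the downstream
feature/statistics pipeline has a recoverable ground truth.

All randomness is driven by ``numpy.random.SeedSequence`` so outputs are
bit-reproducible for a given configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import Phase, Recording

#: Physiological contraction-rate band (contractions/min) for healthy
#: non-pregnant uteri; configs outside it are accepted but warned about.
PHYSIOLOGICAL_RATE_RANGE = (0.8, 6.0)

#: Spike bursts are gated on where the normalized slow wave exceeds this
#: percentile of itself.
SPIKE_GATE_PERCENTILE = 70.0

#: Band (Hz) of the noise carrier used for spike bursts.
SPIKE_BAND = (0.5, 5.0)

#: Per-channel amplitude decay and lag of the propagation model for
#: electrodes 2..n. Only electrode 1 is analyzed downstream.
CHANNEL_DECAY = 0.85
CHANNEL_LAG_S = 2.0


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic recording (amplitudes in uV)."""

    phase: Phase = Phase.UNKNOWN
    contraction_rate: float = 2.4  # contractions/min
    rate_jitter: float = 0.0  # fractional sd of rate across recordings
    slow_wave_amplitude: float = 275.0
    amplitude_dispersion: float = 0.0  # log-normal sd across recordings
    modulation_depth: float = 0.5  # peak-to-trough depth of the envelope m(t)
    spike_burst_amplitude: float = 40.0
    drift_amplitude: float = 30.0
    noise_sd: float = 10.0
    mains_amplitude: float = 20.0  # 50 Hz
    cardiac_amplitude: float = 15.0
    cardiac_rate: float = 1.2  # Hz
    respiration_amplitude: float = 25.0
    respiration_rate: float = 0.25  # Hz
    sampling_rate: float = 256.0
    duration: float = 600.0  # s
    n_channels: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        self.phase = Phase.coerce(self.phase)
        self.validate(warn=True)

    def validate(self, warn: bool = False) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise InvalidConfigError(
                f"duration ({self.duration}) and sampling_rate "
                f"({self.sampling_rate}) must be positive"
            )
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError(
                f"duration x sampling_rate must be an integer sample count, got {n}"
            )
        if self.contraction_rate <= 0:
            raise InvalidConfigError(f"contraction_rate must be > 0, got {self.contraction_rate}")
        if self.n_channels < 1:
            raise InvalidConfigError(f"n_channels must be >= 1, got {self.n_channels}")
        for name in (
            "slow_wave_amplitude",
            "spike_burst_amplitude",
            "drift_amplitude",
            "noise_sd",
            "mains_amplitude",
            "cardiac_amplitude",
            "respiration_amplitude",
            "rate_jitter",
            "amplitude_dispersion",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        lo, hi = PHYSIOLOGICAL_RATE_RANGE
        if warn and not lo <= self.contraction_rate <= hi:
            warnings.warn(
                f"contraction_rate {self.contraction_rate}/min is outside the "
                f"physiological range [{lo}, {hi}]",
                UserWarning,
                stacklevel=3,
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def slow_wave_frequency(self) -> float:
        """Contraction fundamental f_c in Hz."""
        return self.contraction_rate / 60.0


def pp_preset(**overrides) -> GeneratorConfig:
    """Default proliferative-phase preset: fast rhythm, moderate amplitude.

    The 2.4 contractions/min fundamental lands on 0.04 Hz, an exact bin of
    the canonical 300 s analysis window.
    """
    cfg = dict(
        phase=Phase.PP,
        contraction_rate=2.4,
        slow_wave_amplitude=275.0,
        rate_jitter=0.10,
        amplitude_dispersion=0.25,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def lp_preset(**overrides) -> GeneratorConfig:
    """Default luteal-phase preset: slow rhythm, high amplitude."""
    cfg = dict(
        phase=Phase.LP,
        contraction_rate=0.4,
        slow_wave_amplitude=600.0,
        rate_jitter=0.10,
        amplitude_dispersion=0.25,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def phase_preset(phase: Phase | str, **overrides) -> GeneratorConfig:
    phase = Phase.coerce(phase)
    if phase is Phase.PP:
        return pp_preset(**overrides)
    if phase is Phase.LP:
        return lp_preset(**overrides)
    raise ValueError(f"no preset for phase {phase!r}")


def _electrode1_signal(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Build the channel-1 waveform. Random draws are amplitude-independent
    so that scaling every amplitude field scales the output linearly."""
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    f_c = config.slow_wave_frequency

    phi = rng.uniform(0.0, 2.0 * np.pi)
    phi_m = rng.uniform(0.0, 2.0 * np.pi)

    # slow positive modulation envelope, mean 1
    if config.modulation_depth > 0:
        m = 1.0 + 0.5 * config.modulation_depth * np.cos(2.0 * np.pi * (f_c / 4.0) * t + phi_m)
    else:
        m = np.ones(n)
    slow_unit = m * np.cos(2.0 * np.pi * f_c * t + phi)  # unit-amplitude slow wave

    # drift: sum of <=3 sinusoids below f_c/4, total amplitude = drift_amplitude
    n_drift = int(rng.integers(1, 4))
    drift_freqs = rng.uniform(f_c / 20.0, f_c / 4.0, size=n_drift)
    drift_phases = rng.uniform(0.0, 2.0 * np.pi, size=n_drift)
    weights = rng.uniform(0.5, 1.0, size=n_drift)
    weights /= weights.sum()
    drift_unit = np.zeros(n)
    for fd, pd_, w in zip(drift_freqs, drift_phases, weights):
        drift_unit += w * np.sin(2.0 * np.pi * fd * t + pd_)

    # artifact tone phases
    phi_mains, phi_card, phi_resp = rng.uniform(0.0, 2.0 * np.pi, size=3)

    # spike bursts: bandpassed white noise gated where the slow wave is high
    carrier = rng.standard_normal(n)
    nyq = config.sampling_rate / 2.0
    if SPIKE_BAND[1] < nyq:
        sos = sps.butter(4, SPIKE_BAND, btype="bandpass", fs=config.sampling_rate, output="sos")
        carrier = sps.sosfilt(sos, carrier)
    rms = np.sqrt(np.mean(carrier**2))
    if rms > 0:
        carrier = carrier / rms
    gate = slow_unit > np.percentile(slow_unit, SPIKE_GATE_PERCENTILE)

    noise = rng.standard_normal(n)

    x = config.slow_wave_amplitude * slow_unit
    x = x + config.spike_burst_amplitude * carrier * gate
    x = x + config.drift_amplitude * drift_unit
    x = x + config.mains_amplitude * np.sin(2.0 * np.pi * 50.0 * t + phi_mains)
    x = x + config.cardiac_amplitude * np.sin(2.0 * np.pi * config.cardiac_rate * t + phi_card)
    x = x + config.respiration_amplitude * np.sin(
        2.0 * np.pi * config.respiration_rate * t + phi_resp
    )
    x = x + config.noise_sd * noise
    return x


def generate_recording(config: GeneratorConfig) -> Recording:
    """Generate one multichannel recording from ``config``.

    Channel 1 carries the full signal model; channels 2..n are amplitude-
    decayed, time-lagged copies of channel 1 plus independent white noise.
    Output is fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    base = _electrode1_signal(config, rng)

    lag_samples = int(round(CHANNEL_LAG_S * config.sampling_rate))
    channels = np.empty((config.n_channels, config.n_samples))
    channels[0] = base
    for k in range(1, config.n_channels):
        shifted = np.roll(base, k * lag_samples)
        channels[k] = CHANNEL_DECAY**k * shifted + config.noise_sd * rng.standard_normal(
            config.n_samples
        )

    return Recording(
        samples=channels,
        sampling_rate=config.sampling_rate,
        channel_labels=[f"E{i + 1}" for i in range(config.n_channels)],
        phase=config.phase,
        recording_id=f"{config.phase.value}-seed{config.seed}",
        patient_id="",
    )


def _draw_recording_config(
    preset: GeneratorConfig, child: np.random.SeedSequence, index: int
) -> GeneratorConfig:
    """Per-recording parameter draw: jittered rate, log-normal amplitude."""
    rng = np.random.default_rng(child)
    z_rate, z_amp = rng.standard_normal(2)
    rate = preset.contraction_rate * max(1e-3, 1.0 + preset.rate_jitter * z_rate)
    amp = preset.slow_wave_amplitude * np.exp(preset.amplitude_dispersion * z_amp)
    rec_seed = int(child.generate_state(1, dtype=np.uint32)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # jitter may leave the band
        cfg = replace(
            preset,
            contraction_rate=rate,
            slow_wave_amplitude=amp,
            seed=rec_seed,
        )
    return cfg


def generate_cohort(
    preset_pp: GeneratorConfig,
    preset_lp: GeneratorConfig,
    n_pp: int = 11,
    n_lp: int = 15,
    seed: int = 0,
) -> list[Recording]:
    """Generate a labeled PP/LP cohort (default sizes 11 and 15).

    Child seeds are spawned from ``SeedSequence(seed)`` indexed by recording
    number (PP recordings first), so cohorts are reproducible across
    platforms and independent of generation order.
    """
    if n_pp < 1 or n_lp < 1:
        raise ValueError("cohort sizes must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_pp + n_lp)
    recordings: list[Recording] = []
    for i in range(n_pp + n_lp):
        preset = preset_pp if i < n_pp else preset_lp
        cfg = _draw_recording_config(preset, children[i], i)
        rec = generate_recording(cfg)
        within = i if i < n_pp else i - n_pp
        rec.recording_id = f"{preset.phase.value}-{within:03d}"
        rec.patient_id = f"sim{i:03d}"
        recordings.append(rec)
    return recordings
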