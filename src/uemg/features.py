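"""Per-segment features: three amplitude and three spectral scalars.

Amplitude features (RMS, peak, peak-to-peak voltage) are computed directly on
the preprocessed time samples. Spectral features (peak, mean and median
frequency) are computed from a single unwindowed one-sided periodogram of the
full segment — no Welch averaging or tapering, so the frequency resolution is
exactly 1/duration.

The periodogram is scaled so that the one-sided power sums to the mean square
of the time signal (Parseval). The DC bin is always excluded from spectral
features, and by default the analyzed band is (0, 0.1 Hz]: content above the
preprocessing cutoff is numerical residue and must not perturb the
power-weighted mean. Pass ``band=None`` plus ``full_band=True`` semantics via
an explicit band to analyze the full grid.

A zero (or all-equal) segment has no defined spectral features; these are
reported as NaN, never as 0, and callers must exclude them from statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Phase, Segment

#: Default upper edge (Hz) of the spectral-feature band, matching the
#: preprocessing lowpass cutoff.
DEFAULT_BAND_HIGH_HZ = 0.1

FEATURE_NAMES = ["v_rms_uV", "v_peak_uV", "v_pp_uV", "f_peak_hz", "f_mean_hz", "f_median_hz"]
AMPLITUDE_FEATURES = FEATURE_NAMES[:3]
SPECTRAL_FEATURES = FEATURE_NAMES[3:]


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on the DFT grid (power in uV^2)."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have the same shape")

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


def rms_voltage(segment: Segment) -> float:
    """Root-mean-square voltage sqrt(sum(V^2)/N)."""
    if segment.n_samples < 1:
        raise ValueError("empty segment")
    return float(np.sqrt(np.mean(segment.samples**2)))


def peak_voltage(segment: Segment) -> float:
    """max |V[n]|."""
    if segment.n_samples < 1:
        raise ValueError("empty segment")
    return float(np.max(np.abs(segment.samples)))


def peak_to_peak_voltage(segment: Segment) -> float:
    """max(V) - min(V)."""
    if segment.n_samples < 1:
        raise ValueError("empty segment")
    return float(np.max(segment.samples) - np.min(segment.samples))


def periodogram(segment: Segment) -> PowerSpectrum:
    """Full one-sided periodogram (DC through Nyquist), Parseval-scaled."""
    x = segment.samples
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    # double interior bins so one-sided power sums to mean(x^2)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / segment.sampling_rate)
    return PowerSpectrum(frequencies=freqs, power=power, resolution=segment.sampling_rate / n)


def power_spectrum(
    segment: Segment,
    band: tuple[float, float] | None = None,
) -> PowerSpectrum:
    """Periodogram restricted to ``band`` (inclusive at both edges).

    Default band is [resolution, 0.1 Hz]: the DC bin is excluded and the
    upper edge matches the preprocessing lowpass cutoff.
    """
    full = periodogram(segment)
    nyquist = segment.sampling_rate / 2.0
    if band is None:
        band = (full.resolution, DEFAULT_BAND_HIGH_HZ)
    f_lo, f_hi = band
    if f_lo < 0 or f_hi > nyquist + 1e-12 or f_lo > f_hi:
        raise ValueError(f"band {band} outside [0, Nyquist={nyquist}] or inverted")
    eps = full.resolution * 1e-9
    mask = (full.frequencies >= f_lo - eps) & (full.frequencies <= f_hi + eps)
    return PowerSpectrum(
        frequencies=full.frequencies[mask],
        power=full.power[mask],
        resolution=full.resolution,
    )


def peak_frequency(spectrum: PowerSpectrum) -> float:
    """Frequency of the maximal power bin; ties break toward lower frequency."""
    if spectrum.power.size == 0:
        raise ValueError("empty spectrum")
    if spectrum.total_power <= 0:
        raise ValueError("peak frequency undefined for an all-zero spectrum")
    return float(spectrum.frequencies[int(np.argmax(spectrum.power))])


def mean_frequency(spectrum: PowerSpectrum) -> float:
    """Power-weighted mean frequency sum(f P) / sum(P)."""
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("mean frequency undefined for zero total power")
    return float(np.sum(spectrum.frequencies * spectrum.power) / total)


def median_frequency(spectrum: PowerSpectrum) -> float:
    """Smallest grid frequency where cumulative power reaches half the total.

    Left-bin convention, no interpolation: on a discrete grid the exact
    equal-halves balance rarely holds.
    """
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("median frequency undefined for zero total power")
    cum = np.cumsum(spectrum.power)
    idx = int(np.searchsorted(cum, total / 2.0 - total * 1e-12))
    return float(spectrum.frequencies[idx])


@dataclass
class FeatureVector:
    """The six per-segment features plus provenance. NaN marks undefined."""

    v_rms_uV: float
    v_peak_uV: float
    v_pp_uV: float
    f_peak_hz: float
    f_mean_hz: float
    f_median_hz: float
    recording_id: str = ""
    segment_index: int = 0
    phase: Phase = Phase.UNKNOWN

    def as_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "segment_index": self.segment_index,
            "phase": self.phase.value,
            **{name: getattr(self, name) for name in FEATURE_NAMES},
        }


def extract_features(segment: Segment, band: tuple[float, float] | None = None) -> FeatureVector:
    """Compute all six features of a preprocessed segment.

    Spectral features of a signal with no in-band power are NaN.
    """
    v_rms = rms_voltage(segment)
    v_peak = peak_voltage(segment)
    v_pp = peak_to_peak_voltage(segment)
    spectrum = power_spectrum(segment, band=band)
    if spectrum.power.size == 0 or spectrum.total_power <= 0:
        f_pk = f_mn = f_md = math.nan
    else:
        f_pk = peak_frequency(spectrum)
        f_mn = mean_frequency(spectrum)
        f_md = median_frequency(spectrum)
    return FeatureVector(
        v_rms_uV=v_rms,
        v_peak_uV=v_peak,
        v_pp_uV=v_pp,
        f_peak_hz=f_pk,
        f_mean_hz=f_mn,
        f_median_hz=f_md,
        recording_id=segment.source_recording_id,
        segment_index=segment.segment_index,
        phase=segment.phase,
    )


def feature_table(
    segments: list[Segment], band: tuple[float, float] | None = None
) -> pd.DataFrame:
    """One row per segment: provenance columns then the six feature columns."""
    rows = [extract_features(s, band=band).as_dict() for s in segments]
    cols = ["recording_id", "segment_index", "phase", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)
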