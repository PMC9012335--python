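"""Preprocessing chain for slow-wave analysis.

Per segment, in order: mean subtraction, eighth-order 0.1 Hz Butterworth
lowpass, x8 decimation (256 Hz -> 32 Hz). The lowpass doubles as the
anti-aliasing filter, so decimation keeps every ``factor``-th sample with no
additional filtering.

The filter is realized as cascaded second-order sections: at a normalized
cutoff of 0.1/128 a transfer-function realization of an 8th-order filter is
numerically unstable. The default is a causal single pass with steady-state
initial conditions (state matched to the segment's first sample), which
preserves the stated 8th-order magnitude response; zero-phase filtering is
available via ``zero_phase=True`` at the cost of doubling the effective
order. The first ~1/cutoff seconds of each filtered segment remain partially
transient; no settling-time discard is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Recording, Segment


@dataclass
class PreprocessParams:
    cutoff_hz: float = 0.1
    order: int = 8
    downsample_factor: int = 8
    segment_duration_s: float = 300.0
    max_segments_per_recording: int = 2
    channel: int = 0  # 0-based index; electrode 1
    zero_phase: bool = False
    settle_discard_s: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def segment_recording(
    recording: Recording,
    channel: int = 0,
    segment_duration: float = 300.0,
    max_segments: int = 2,
    settle_discard_s: float = 0.0,
) -> list[Segment]:
    """Cut one channel into consecutive non-overlapping full-length windows.

    Windows start at the first sample (optionally after ``settle_discard_s``),
    trailing partial windows are discarded, and at most ``max_segments``
    windows are returned.
    """
    if segment_duration <= 0:
        raise ValueError(f"segment_duration must be positive, got {segment_duration}")
    if not 0 <= channel < recording.n_channels:
        raise IndexError(
            f"channel {channel} out of range for {recording.n_channels}-channel recording"
        )
    x = recording.samples[channel]
    start = int(round(settle_discard_s * recording.sampling_rate))
    window = int(round(segment_duration * recording.sampling_rate))
    segments: list[Segment] = []
    idx = 0
    while start + window <= x.size and len(segments) < max_segments:
        segments.append(
            Segment(
                samples=x[start : start + window].copy(),
                sampling_rate=recording.sampling_rate,
                source_recording_id=recording.recording_id,
                segment_index=idx,
                phase=recording.phase,
            )
        )
        start += window
        idx += 1
    return segments


def subtract_mean(segment: Segment) -> Segment:
    """Remove the segment mean: V'[n] = V[n] - mean(V)."""
    if segment.n_samples < 1:
        raise ValueError("cannot subtract mean of an empty segment")
    return segment.with_samples(segment.samples - segment.samples.mean())


def lowpass_filter(
    segment: Segment,
    cutoff: float = 0.1,
    order: int = 8,
    zero_phase: bool = False,
) -> Segment:
    """Butterworth lowpass (cascaded second-order sections), -3 dB at ``cutoff``."""
    nyquist = segment.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=segment.sampling_rate, output="sos")
    x = segment.samples
    if zero_phase:
        # default padlen is far too short for cutoffs this far below Nyquist;
        # pad ~3 filter time constants, and reflect without sign flip so the
        # edges are not anchored to the raw endpoint samples
        padlen = min(x.size - 1, int(round(3.0 * segment.sampling_rate / cutoff)))
        y = sps.sosfiltfilt(sos, x, padlen=padlen, padtype="even")
    else:
        zi = sps.sosfilt_zi(sos) * x[0]
        y, _ = sps.sosfilt(sos, x, zi=zi)
    return segment.with_samples(y)


def downsample(segment: Segment, factor: int = 8) -> Segment:
    """Plain decimation: keep every ``factor``-th sample starting at the first.

    The caller is responsible for having lowpass-filtered the segment first.
    """
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return segment.with_samples(segment.samples.copy())
    return segment.with_samples(
        segment.samples[::factor], sampling_rate=segment.sampling_rate / factor
    )


def preprocess_segment(segment: Segment, params: PreprocessParams | None = None) -> Segment:
    """subtract_mean -> lowpass_filter -> downsample, in that order."""
    params = params or PreprocessParams()
    out = subtract_mean(segment)
    out = lowpass_filter(out, cutoff=params.cutoff_hz, order=params.order, zero_phase=params.zero_phase)
    return downsample(out, factor=params.downsample_factor)


def preprocess_recording(
    recording: Recording, params: PreprocessParams | None = None
) -> list[Segment]:
    """Segment one channel of a recording and preprocess every segment."""
    params = params or PreprocessParams()
    segments = segment_recording(
        recording,
        channel=params.channel,
        segment_duration=params.segment_duration_s,
        max_segments=params.max_segments_per_recording,
        settle_discard_s=params.settle_discard_s,
    )
    return [preprocess_segment(s, params) for s in segments]
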