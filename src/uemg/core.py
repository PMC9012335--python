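"""Shared domain types: recordings, segments, and cycle-phase labels.

All voltages are microvolts (uV) and all sampling rates Hz throughout the
package; nothing rescales units internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np


class Phase(str, Enum):
    """Menstrual-cycle phase label attached to recordings and segments."""

    PP = "PP"  # proliferative phase
    LP = "LP"  # luteal phase
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: "Phase | str | None") -> "Phase":
        if value is None:
            return cls.UNKNOWN
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            return cls[str(value).upper()] if str(value).upper() in cls.__members__ else cls.UNKNOWN


@dataclass
class Recording:
    """Multichannel voltage recording (channels x samples, uV)."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    phase: Phase = Phase.UNKNOWN
    recording_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.phase = Phase.coerce(self.phase)
        if not self.channel_labels:
            self.channel_labels = [f"E{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class Segment:
    """Single-channel analysis window V[n], n = 1..N."""

    samples: np.ndarray
    sampling_rate: float
    source_recording_id: str = ""
    segment_index: int = 0
    phase: Phase = Phase.UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.phase = Phase.coerce(self.phase)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray, sampling_rate: float | None = None) -> "Segment":
        """Copy of this segment with new sample data (metadata preserved)."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        if sampling_rate is not None:
            out.sampling_rate = sampling_rate
        return out
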