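"""Recording I/O: CSV with a YAML metadata sidecar, and EDF.

CSV stores one column per channel with a header row; the sample period and
phase/patient metadata live in a ``<name>.yaml`` sidecar next to the data
file. A missing sidecar degrades gracefully: the recording loads with phase
unknown (sampling rate defaults to 256 Hz) and a warning is emitted.

EDF (European Data Format) support is a minimal self-contained
implementation of the published fixed-layout spec: 256-byte main header,
256 bytes per signal, then little-endian int16 data records, with physical
scaling from the per-signal physical/digital ranges. Round-trips are exact
to within one 16-bit quantization step of the physical range. Phase and
patient metadata ride in the recording-identification header field.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Phase, Recording


class RecordingIOError(ValueError):
    """Malformed recording file."""


# ---------------------------------------------------------------------------
# CSV + YAML sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Write samples as CSV (one column per channel) plus a YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "sampling_rate_hz": float(recording.sampling_rate),
        "phase": recording.phase.value,
        "recording_id": recording.recording_id,
        "patient_id": recording.patient_id,
        "channel_labels": list(recording.channel_labels),
        "units": "uV",
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message shaping
        raise RecordingIOError(f"cannot parse CSV samples in {path}: {exc}") from exc
    if df.empty:
        raise RecordingIOError(f"no samples in {path}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        if "sampling_rate_hz" not in meta:
            raise RecordingIOError(f"sidecar {sidecar} missing field 'sampling_rate_hz'")
        fs = float(meta["sampling_rate_hz"])
        phase = Phase.coerce(meta.get("phase"))
        rec_id = str(meta.get("recording_id", path.stem))
        patient = str(meta.get("patient_id", ""))
    else:
        warnings.warn(
            f"no metadata sidecar for {path}; assuming 256 Hz, phase unknown",
            UserWarning,
            stacklevel=2,
        )
        fs, phase, rec_id, patient = 256.0, Phase.UNKNOWN, path.stem, ""
    return Recording(
        samples=df.to_numpy(dtype=float).T,
        sampling_rate=fs,
        channel_labels=[str(c) for c in df.columns],
        phase=phase,
        recording_id=rec_id,
        patient_id=patient,
    )


# ---------------------------------------------------------------------------
# EDF


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as EDF with one data record per second."""
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise RecordingIOError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal (1 s records)
    n_sig = recording.n_channels
    n_rec = recording.n_samples // spr
    if n_rec * spr != recording.n_samples:
        raise RecordingIOError("EDF export requires a whole number of 1 s records")

    data = recording.samples[:, : n_rec * spr]
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid degenerate scaling for flat channels
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / gain[:, None] + dig_min).astype("<i2")

    rec_info = f"phase={recording.phase.value} id={recording.recording_id}"
    header = b"".join(
        [
            _ascii_field("0", 8),  # version
            _ascii_field(recording.patient_id or "X", 80),
            _ascii_field(rec_info, 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_sig), 8),
            _ascii_field("", 44),
            _ascii_field(n_rec, 8),
            _ascii_field(1, 8),  # record duration, s
            _ascii_field(n_sig, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_ascii_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_ascii_field("intrauterine electrode", 80) for _ in range(n_sig)),
            b"".join(_ascii_field("uV", 8) for _ in range(n_sig)),
            b"".join(_ascii_field(f"{phys_min[i]:.8g}"[:8], 8) for i in range(n_sig)),
            b"".join(_ascii_field(f"{phys_max[i]:.8g}"[:8], 8) for i in range(n_sig)),
            b"".join(_ascii_field(dig_min, 8) for _ in range(n_sig)),
            b"".join(_ascii_field(dig_max, 8) for _ in range(n_sig)),
            b"".join(_ascii_field("", 80) for _ in range(n_sig)),  # prefiltering
            b"".join(_ascii_field(spr, 8) for _ in range(n_sig)),
            b"".join(_ascii_field("", 32) for _ in range(n_sig)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # records interleave signals: all of signal 1's spr samples, then 2, ...
        records = digital.reshape(n_sig, n_rec, spr).transpose(1, 0, 2)
        fh.write(records.tobytes())
    return path


def _parse_field(raw: bytes, start: int, width: int) -> str:
    return raw[start : start + width].decode("ascii", errors="replace").strip()


def read_recording_edf(path: str | Path) -> Recording:
    path = Path(path)
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise RecordingIOError(f"{path}: truncated EDF header")
    try:
        n_rec = int(_parse_field(raw, 236, 8))
        record_dur = float(_parse_field(raw, 244, 8))
        n_sig = int(_parse_field(raw, 252, 4))
    except ValueError as exc:
        raise RecordingIOError(f"{path}: malformed EDF header counts: {exc}") from exc
    rec_info = _parse_field(raw, 88, 80)
    patient = _parse_field(raw, 8, 80)

    sig = raw[256 : 256 * (1 + n_sig)]

    def sig_fields(offset: int, width: int) -> list[str]:
        base = offset * n_sig
        return [
            sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(n_sig)
        ]

    labels = sig_fields(0, 16)
    try:
        phys_min = np.array([float(v) for v in sig_fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([int(v) for v in sig_fields(16 + 80 + 8 + 8 + 8, 8)])
        dig_max = np.array([int(v) for v in sig_fields(16 + 80 + 8 + 8 + 8 + 8, 8)])
        spr = [int(v) for v in sig_fields(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
    except ValueError as exc:
        raise RecordingIOError(f"{path}: malformed EDF signal header: {exc}") from exc

    if len(set(spr)) != 1:
        raise RecordingIOError(f"{path}: mixed per-signal sampling rates are unsupported")
    spr0 = spr[0]
    fs = spr0 / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=256 * (1 + n_sig))
    expected = n_rec * n_sig * spr0
    if body.size < expected:
        raise RecordingIOError(f"{path}: data area holds {body.size} samples, expected {expected}")
    records = body[:expected].reshape(n_rec, n_sig, spr0).transpose(1, 0, 2)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    samples = (records.reshape(n_sig, -1).astype(float) - dig_min[:, None]) * gain[
        :, None
    ] + phys_min[:, None]

    phase = Phase.UNKNOWN
    rec_id = path.stem
    for token in rec_info.split():
        if token.startswith("phase="):
            phase = Phase.coerce(token[len("phase=") :])
        elif token.startswith("id="):
            rec_id = token[len("id=") :]
    return Recording(
        samples=samples,
        sampling_rate=fs,
        channel_labels=labels,
        phase=phase,
        recording_id=rec_id,
        patient_id=patient if patient != "X" else "",
    )


# ---------------------------------------------------------------------------
# dispatch


def write_recording(recording: Recording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return write_recording_csv(recording, path)
    if fmt == "edf":
        return write_recording_edf(recording, path)
    raise ValueError(f"unsupported recording format {fmt!r} (use 'csv' or 'edf')")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return read_recording_csv(path)
    if fmt == "edf":
        return read_recording_edf(path)
    raise ValueError(f"unsupported recording format {fmt!r} (use 'csv' or 'edf')")
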