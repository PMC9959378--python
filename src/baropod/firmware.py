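"""Microcontroller-side link logic, emulated.

Covers the four firmware behaviors that shape the data stream:

* element-wise conversion of a 16-channel 12-bit ADC frame to the 0–100%
  scale,
* the noise gate — a frame whose maximum percent is strictly below 10 is
  treated as no traffic and never transmitted,
* the 150 ms transmission schedule (400 slots per minute, at least two per
  step even at an elite 170–180 steps-per-minute cadence),
* the single-byte wire codec: each percent value is sent as the ASCII
  character with that codepoint (40 goes out as ``'('``).

Wire format (fixed 18 bytes per frame)::

    +--------+----------------------+-----------+
    | header |  16 payload bytes    | delimiter |
    | 1 byte |  value -> codepoint  |   0x0A    |
    +--------+----------------------+-----------+

The header byte is 0xD0 for the left insole and 0xD1 for the right (the high
nibble 0xD is the format version mark).  Header codepoints sit above any
legal payload value, so resynchronization after corruption scans for a
header byte; the newline delimiter is only interpreted positionally, since
codepoint 10 is also a legal payload value.  Frames carry no timestamp — the
receiving side timestamps on arrival, exactly as the phone app does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .calibration import CalibrationCurve, reading_to_percent

__all__ = [
    "AdcFrame",
    "PercentVector",
    "FirmwareConfig",
    "DEFAULT_CONFIG",
    "FRAME_LENGTH",
    "HEADER_LEFT",
    "HEADER_RIGHT",
    "DELIMITER",
    "FrameError",
    "DecodeResult",
    "to_percent_vector",
    "gate",
    "schedule_slots",
    "check_sampling_adequacy",
    "encode_frame",
    "encode_stream",
    "decode_stream",
    "bits_view",
]

N_SENSORS = 16
HEADER_LEFT = 0xD0
HEADER_RIGHT = 0xD1
DELIMITER = 0x0A
FRAME_LENGTH = 1 + N_SENSORS + 1  # header + payload + delimiter = 18

Foot = Literal["left", "right"]

_HEADER_BY_FOOT = {"left": HEADER_LEFT, "right": HEADER_RIGHT}
_FOOT_BY_HEADER = {v: k for k, v in _HEADER_BY_FOOT.items()}


class LinkError(ValueError):
    """Invalid frame, vector or configuration."""


@dataclass(frozen=True)
class AdcFrame:
    """One timestamped vector of 16 quantized 12-bit sensor readings."""

    timestamp_ms: int
    readings: tuple[int, ...]
    foot: Foot = "left"

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(int(r) for r in self.readings))
        if len(self.readings) != N_SENSORS:
            raise LinkError(f"expected {N_SENSORS} readings, got {len(self.readings)}")
        if any(not 0 <= r <= 4095 for r in self.readings):
            raise LinkError(f"readings must be in [0, 4095]: {self.readings}")
        if self.foot not in _HEADER_BY_FOOT:
            raise LinkError(f"foot must be 'left' or 'right', got {self.foot!r}")


@dataclass(frozen=True)
class PercentVector:
    """16 integer pressures on the 0–100% scale — the unit of transmission."""

    timestamp_ms: int
    values: tuple[int, ...]
    foot: Foot = "left"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        if len(self.values) != N_SENSORS:
            raise LinkError(f"expected {N_SENSORS} values, got {len(self.values)}")
        if any(not 0 <= v <= 100 for v in self.values):
            raise LinkError(f"percent values must be in [0, 100]: {self.values}")
        if self.foot not in _HEADER_BY_FOOT:
            raise LinkError(f"foot must be 'left' or 'right', got {self.foot!r}")


@dataclass(frozen=True)
class FirmwareConfig:
    gate_threshold_percent: int = 10
    period_ms: int = 150
    payload_capacity: int = 255

    def __post_init__(self) -> None:
        if not 0 <= self.gate_threshold_percent <= 100:
            raise LinkError(
                f"gate threshold must be in [0, 100], got {self.gate_threshold_percent}"
            )
        if not self.period_ms > 0:
            raise LinkError(f"period_ms must be positive, got {self.period_ms}")


DEFAULT_CONFIG = FirmwareConfig()


def to_percent_vector(
    frame: AdcFrame,
    curve: CalibrationCurve,
    table: np.ndarray | None = None,
) -> PercentVector:
    """Element-wise percent conversion, preserving timestamp and foot tag.

    ``table`` may be a precomputed :func:`baropod.calibration.percent_table`
    lookup for bulk conversion; the result is identical.
    """
    if table is not None:
        values = tuple(int(table[r]) for r in frame.readings)
    else:
        values = tuple(reading_to_percent(curve, r) for r in frame.readings)
    return PercentVector(timestamp_ms=frame.timestamp_ms, values=values, foot=frame.foot)


def gate(vector: PercentVector, config: FirmwareConfig = DEFAULT_CONFIG) -> bool:
    """Transmit decision: False (suppress) iff max(values) is strictly below
    the threshold — such a frame is considered noise, not traffic."""
    return max(vector.values) >= config.gate_threshold_percent


def schedule_slots(duration_ms: int, config: FirmwareConfig = DEFAULT_CONFIG) -> int:
    """Number of transmission slots in a window (floor of duration/period)."""
    if duration_ms < 0:
        raise LinkError(f"duration_ms must be non-negative, got {duration_ms}")
    return int(duration_ms) // config.period_ms


def check_sampling_adequacy(
    cadence_spm: float, config: FirmwareConfig = DEFAULT_CONFIG
) -> bool:
    """Nyquist check: at least two transmission slots per step at this cadence."""
    if not cadence_spm > 0:
        raise LinkError(f"cadence must be positive, got {cadence_spm}")
    return schedule_slots(60_000, config) >= 2 * cadence_spm


# ---------------------------------------------------------------------------
# Codec

def encode_frame(
    vector: PercentVector, config: FirmwareConfig = DEFAULT_CONFIG
) -> bytes:
    """Encode one vector as an 18-byte wire frame.

    Each value becomes the single byte with that codepoint (the char cast the
    firmware performs), so 40 travels as ``'('``.
    """
    if any(v > config.payload_capacity for v in vector.values):
        raise LinkError(
            f"payload value exceeds single-byte capacity {config.payload_capacity}"
        )
    return bytes([_HEADER_BY_FOOT[vector.foot], *vector.values, DELIMITER])


def encode_stream(
    vectors: Iterable[PercentVector], config: FirmwareConfig = DEFAULT_CONFIG
) -> bytes:
    """Concatenate the wire frames of a vector sequence."""
    return b"".join(encode_frame(v, config) for v in vectors)


@dataclass(frozen=True)
class FrameError:
    """A decoding anomaly: truncated frame, bad header, or out-of-range payload."""

    offset: int
    kind: Literal["truncated", "bad_header", "out_of_range"]
    detail: str


@dataclass
class DecodeResult:
    frames: list[PercentVector] = field(default_factory=list)
    errors: list[FrameError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def decode_stream(
    data: bytes,
    *,
    timestamps: Sequence[int] | None = None,
    period_ms: int = 150,
    start_ms: int = 0,
    strict: bool = False,
) -> DecodeResult:
    """Parse a byte stream back into percent vectors.

    Frames are fixed-length; a byte that is not a valid header causes a scan
    forward to the next header byte (resynchronization) and a ``bad_header``
    error record.  An incomplete trailing frame is reported as ``truncated``,
    never silently dropped.  ``timestamps`` supplies per-frame arrival times;
    without them frames are stamped ``start_ms + i·period_ms``.  Payload bytes
    above 100 are clamped-and-flagged by default; ``strict`` rejects the frame.
    """
    result = DecodeResult()
    pos = 0
    n = len(data)
    while pos < n:
        header = data[pos]
        if header not in _FOOT_BY_HEADER:
            skip_to = pos + 1
            while skip_to < n and data[skip_to] not in _FOOT_BY_HEADER:
                skip_to += 1
            result.errors.append(
                FrameError(
                    offset=pos,
                    kind="bad_header",
                    detail=f"skipped {skip_to - pos} byte(s) seeking a header",
                )
            )
            pos = skip_to
            continue
        if pos + FRAME_LENGTH > n:
            result.errors.append(
                FrameError(
                    offset=pos,
                    kind="truncated",
                    detail=f"{n - pos} of {FRAME_LENGTH} bytes present",
                )
            )
            break
        payload = data[pos + 1 : pos + 1 + N_SENSORS]
        bad = [v for v in payload if v > 100]
        if bad:
            err = FrameError(
                offset=pos,
                kind="out_of_range",
                detail=f"payload values above 100: {sorted(set(bad))}",
            )
            if strict:
                raise LinkError(err.detail)
            result.errors.append(err)
        i = len(result.frames)
        t = int(timestamps[i]) if timestamps is not None else start_ms + i * period_ms
        result.frames.append(
            PercentVector(
                timestamp_ms=t,
                values=tuple(min(v, 100) for v in payload),
                foot=_FOOT_BY_HEADER[header],
            )
        )
        pos += FRAME_LENGTH
    return result


def bits_view(data: bytes) -> str:
    """Big-endian bit string of a byte sequence (``b"AT"`` → ``0100000101010100``)."""
    return "".join(f"{byte:08b}" for byte in data)
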