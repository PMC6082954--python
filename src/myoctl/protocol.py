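"""Telemetry codecs between the prosthesis controller and the terminal.

Two fixed-length frame formats travel over the (abstracted) serial link:

* threshold mode, every 100 ms, 5 bytes — a start byte, then the envelope
  feature and both thresholds each quantized to 256 steps over 0–0.25 V,
  then a modulo-256 checksum of the three payload bytes;
* pattern mode, every 10 ms, 66 bytes — a start byte, the 16-dimensional
  band-power feature as single-precision floats, and a terminator byte.

The start/terminator byte values and float endianness are configuration,
not protocol substance.  A resynchronizer recovers well-formed frames from
a noisy byte stream, and a fixed-capacity ring buffer models the terminal's
scrolling graph.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "THRESHOLD_START",
    "PATTERN_START",
    "PATTERN_TERMINATOR",
    "Q_FULL_SCALE",
    "Q_STEP",
    "FramingError",
    "quantize_volts",
    "dequantize_volts",
    "encode_threshold_frame",
    "decode_threshold_frame",
    "encode_pattern_frame",
    "decode_pattern_frame",
    "resync_stream",
    "DecodedThresholdFrame",
    "GraphBuffer",
]

THRESHOLD_START = 0xA5
PATTERN_START = 0xA6
PATTERN_TERMINATOR = 0x0A
FLOAT_FMT = "<16f"  # IEEE-754 single precision, little-endian

Q_FULL_SCALE = 0.25  # V; telemetry quantization range
Q_STEP = Q_FULL_SCALE / 256.0

THRESHOLD_FRAME_LEN = 5
PATTERN_FRAME_LEN = 66


class FramingError(ValueError):
    """Frame has wrong length, start byte or terminator."""


def quantize_volts(v: float) -> int:
    """256-step quantization over [0, 0.25) V, floor with clamping."""
    level = int(np.floor(np.clip(v, 0.0, Q_FULL_SCALE) / Q_STEP))
    return min(level, 255)


def dequantize_volts(level: int) -> float:
    """Bin-center voltage of a quantization level."""
    if not (0 <= level <= 255):
        raise ValueError("level must lie in 0..255")
    return (level + 0.5) * Q_STEP


@dataclass(frozen=True)
class DecodedThresholdFrame:
    feature_q: int
    theta_high_q: int
    theta_low_q: int
    valid: bool


def encode_threshold_frame(y: float, theta_high: float, theta_low: float) -> bytes:
    """5-byte frame: start, feature, θ_high, θ_low, checksum (sum mod 256)."""
    fq, hq, lq = quantize_volts(y), quantize_volts(theta_high), quantize_volts(theta_low)
    return bytes([THRESHOLD_START, fq, hq, lq, (fq + hq + lq) % 256])


def decode_threshold_frame(frame: bytes) -> DecodedThresholdFrame:
    """Decode a 5-byte threshold frame; a bad checksum flags it invalid."""
    if len(frame) != THRESHOLD_FRAME_LEN:
        raise FramingError(f"threshold frame must be {THRESHOLD_FRAME_LEN} bytes")
    if frame[0] != THRESHOLD_START:
        raise FramingError("bad start byte")
    fq, hq, lq, chk = frame[1], frame[2], frame[3], frame[4]
    return DecodedThresholdFrame(fq, hq, lq, valid=((fq + hq + lq) % 256 == chk))


def encode_pattern_frame(features) -> bytes:
    """66-byte frame: start, 16 single-precision floats, terminator."""
    x = np.asarray(features, dtype=float)
    if x.shape != (16,):
        raise ValueError("feature vector must have 16 entries")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    return bytes([PATTERN_START]) + struct.pack(FLOAT_FMT, *x) + bytes([PATTERN_TERMINATOR])


def decode_pattern_frame(frame: bytes) -> np.ndarray:
    """Decode a 66-byte pattern frame to its 16 feature values."""
    if len(frame) != PATTERN_FRAME_LEN:
        raise FramingError(f"pattern frame must be {PATTERN_FRAME_LEN} bytes")
    if frame[0] != PATTERN_START:
        raise FramingError("bad start byte")
    if frame[-1] != PATTERN_TERMINATOR:
        raise FramingError("missing terminator")
    return np.array(struct.unpack(FLOAT_FMT, frame[1:-1]), dtype=np.float32)


def resync_stream(data: bytes, kind: str = "threshold") -> list:
    """Recover every well-formed frame embedded in a noisy byte stream.

    Scans for the start byte, validates the candidate frame (checksum for
    threshold frames, terminator for pattern frames) and either consumes it
    or advances one byte.  Garbage between frames is skipped; recovery is
    lossy by design.
    """
    if kind == "threshold":
        start, length = THRESHOLD_START, THRESHOLD_FRAME_LEN
    elif kind == "pattern":
        start, length = PATTERN_START, PATTERN_FRAME_LEN
    else:
        raise ValueError("kind must be 'threshold' or 'pattern'")
    frames = []
    i = 0
    while i + length <= len(data):
        if data[i] != start:
            i += 1
            continue
        candidate = data[i : i + length]
        try:
            if kind == "threshold":
                decoded = decode_threshold_frame(candidate)
                ok = decoded.valid
            else:
                decoded = decode_pattern_frame(candidate)
                ok = True
        except FramingError:
            ok = False
        if ok:
            frames.append(decoded)
            i += length
        else:
            i += 1
    return frames


class GraphBuffer:
    """Fixed-capacity ring of the newest feature values, plus thresholds.

    Models the terminal's scrolling graph: once full, each push overwrites
    the oldest entry.  ``update_thresholds`` applies the terminal's redraw
    rule — a received threshold replaces the stored one only when it
    differs — and reports whether anything changed.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be at least 1")
        self.capacity = capacity
        self._buf: list = []
        self._next = 0
        self.theta_high_q: int | None = None
        self.theta_low_q: int | None = None

    def __len__(self) -> int:
        return len(self._buf)

    def push(self, value) -> None:
        if len(self._buf) < self.capacity:
            self._buf.append(value)
        else:
            self._buf[self._next] = value
        self._next = (self._next + 1) % self.capacity

    def values(self) -> list:
        """Buffered values, oldest first."""
        if len(self._buf) < self.capacity:
            return list(self._buf)
        return self._buf[self._next :] + self._buf[: self._next]

    def update_thresholds(self, theta_high_q: int, theta_low_q: int) -> bool:
        changed = (theta_high_q, theta_low_q) != (self.theta_high_q, self.theta_low_q)
        if changed:
            self.theta_high_q = theta_high_q
            self.theta_low_q = theta_low_q
        return changed
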