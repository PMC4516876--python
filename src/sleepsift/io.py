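"""File formats: a minimal EDF reader/writer and the tab-separated
annotation files (segment number, event type, times and sample indices)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .errors import ChannelError, FormatError, InputError, ParameterError
from .events import Event

__all__ = [
    "Recording",
    "AnnotationRecord",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
]

SEGMENT_LENGTH_S = 30.0


@dataclass
class Recording:
    """Single-channel recording in physical units (uV)."""

    samples: np.ndarray
    fs: float
    channel_label: str = "C3"
    segment_length_s: float = SEGMENT_LENGTH_S

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")

    @property
    def n_segments(self) -> int:
        """Number of complete segments; a trailing partial window is dropped."""
        return int(len(self.samples) // round(self.segment_length_s * self.fs))

    def segment(self, i: int) -> np.ndarray:
        n = int(round(self.segment_length_s * self.fs))
        if not 0 <= i < self.n_segments:
            raise InputError(f"segment {i} out of range 0..{self.n_segments - 1}")
        return self.samples[i * n : (i + 1) * n]


# ----------------------------------------------------------------------
# EDF (European Data Format), 16-bit integer samples with per-signal
# physical calibration.  Only the subset needed here is implemented:
# continuous recordings, 1-second data records, integer sampling rates.

_HDR_FIXED = 256


def _afield(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"field {text!r} exceeds {width} ascii chars")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    recording: Recording,
    start_date: str = "01.01.00",
    start_time: str = "00.00.00",
) -> None:
    """Write a single-channel EDF file with 1-s records (integer fs only).

    The tail is zero-padded to a whole number of records.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    x = recording.samples
    n_records = max(1, math.ceil(len(x) / spr))
    padded = np.zeros(n_records * spr)
    padded[: len(x)] = x

    phys_max = max(1.0, float(np.ceil(np.max(np.abs(padded)) + 1e-9)))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * gain + dig_min).astype("<i2")

    header_bytes = _HDR_FIXED + 256  # one signal
    with open(path, "wb") as f:
        f.write(_afield("0", 8))
        f.write(_afield("X X X X", 80))
        f.write(_afield("Startdate X X X X", 80))
        f.write(_afield(start_date, 8))
        f.write(_afield(start_time, 8))
        f.write(_afield(str(header_bytes), 8))
        f.write(_afield("", 44))
        f.write(_afield(str(n_records), 8))
        f.write(_afield("1", 8))
        f.write(_afield("1", 4))
        f.write(_afield(recording.channel_label, 16))
        f.write(_afield("AgAgCl electrode", 80))
        f.write(_afield("uV", 8))
        f.write(_afield(f"{phys_min:g}", 8))
        f.write(_afield(f"{phys_max:g}", 8))
        f.write(_afield(str(dig_min), 8))
        f.write(_afield(str(dig_max), 8))
        f.write(_afield("", 80))
        f.write(_afield(str(spr), 8))
        f.write(_afield("", 32))
        f.write(digital.tobytes())


def read_edf(path: str | Path, channel: str | None = None) -> Recording:
    """Read one channel of an EDF file, calibrated to physical units."""
    path = Path(path)
    with open(path, "rb") as f:
        raw = f.read()
    if len(raw) < _HDR_FIXED:
        raise FormatError(f"{path}: truncated EDF header")

    def fixed(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(fixed(236, 8))
        record_dur = float(fixed(244, 8))
        ns = int(fixed(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header ({exc})") from exc
    if ns < 1 or n_records < 1 or record_dur <= 0:
        raise FormatError(f"{path}: invalid EDF header counts")

    sig_hdr_off = _HDR_FIXED
    if len(raw) < sig_hdr_off + ns * 256:
        raise FormatError(f"{path}: truncated signal headers")

    def sigfield(index: int, block: int, width: int) -> str:
        # signal headers are stored field-major: all labels, then all
        # transducers, etc.
        off = sig_hdr_off + block + index * width
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    blocks = np.concatenate([[0], np.cumsum(np.array(widths) * ns)])[:-1]
    labels = [sigfield(i, blocks[0], 16) for i in range(ns)]

    if channel is None:
        idx = 0
    else:
        matches = [i for i, lbl in enumerate(labels) if lbl == channel]
        if not matches:
            raise ChannelError(
                f"channel {channel!r} not in {path.name}; available: {labels}"
            )
        idx = matches[0]

    try:
        phys_min = float(sigfield(idx, blocks[3], 8))
        phys_max = float(sigfield(idx, blocks[4], 8))
        dig_min = int(sigfield(idx, blocks[5], 8))
        dig_max = int(sigfield(idx, blocks[6], 8))
        spr = [int(sigfield(i, blocks[8], 8)) for i in range(ns)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed signal header ({exc})") from exc
    if dig_max == dig_min or phys_max == phys_min:
        raise FormatError(f"{path}: degenerate calibration")

    data_off = sig_hdr_off + ns * 256
    rec_len = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", offset=data_off)
    if len(data) < n_records * rec_len:
        raise FormatError(f"{path}: truncated data records")

    chan = np.empty(n_records * spr[idx])
    pre = sum(spr[:idx])
    for r in range(n_records):
        off = r * rec_len + pre
        chan[r * spr[idx] : (r + 1) * spr[idx]] = data[off : off + spr[idx]]

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    physical = (chan - dig_min) * gain + phys_min
    return Recording(
        samples=physical,
        fs=spr[idx] / record_dur,
        channel_label=labels[idx],
    )


# ----------------------------------------------------------------------
# annotation text files

@dataclass
class AnnotationRecord:
    segment_number: int  # 1-based
    event_type: str
    start_s: float
    end_s: float
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.segment_number < 1:
            raise ParameterError("segment_number is 1-based (>= 1)")
        if not self.start_s < self.end_s:
            raise ParameterError("start_s must precede end_s")


_HEADER = "segment_number\tevent_type\tstart_s\tend_s\tstart_sample\tend_sample"


def write_annotations(events: Sequence[Event], path: str | Path, fs: float) -> None:
    """Tab-separated annotation file; segment numbers are written 1-based."""
    with open(path, "w") as f:
        f.write(_HEADER + "\n")
        for e in sorted(events, key=lambda e: (e.segment_id, e.start_s)):
            f.write(
                f"{e.segment_id + 1}\t{e.kind}\t{e.start_s:.6f}\t{e.end_s:.6f}"
                f"\t{int(round(e.start_s * fs))}\t{int(round(e.end_s * fs))}\n"
            )


def read_annotations(path: str | Path) -> List[Event]:
    """Parse an annotation file back into 0-based-segment events."""
    path = Path(path)
    events: List[Event] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("segment_number"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                seg = int(parts[0])
                kind = parts[1]
                start_s = float(parts[2])
                end_s = float(parts[3])
                int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
            events.append(
                Event(kind=kind, segment_id=seg - 1, start_s=start_s, end_s=end_s)
            )
    return events
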