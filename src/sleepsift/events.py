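"""Typed detection/annotation events on a recording timeline."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

VALID_KINDS = ("spindle", "kcomplex")


@dataclass
class Event:
    """A half-open time interval [start_s, end_s) of one event type.

    peak_value is in uV^2 for spindles (T-F map peak) and uV for
    K-complexes (trough depth, negative).
    """

    kind: str
    segment_id: int
    start_s: float
    end_s: float
    peak_value: float = 0.0
    peak_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ParameterError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ParameterError(
                f"end_s must exceed start_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "Event") -> float:
        """Length of temporal intersection with another event (>= 0)."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))

    def shifted(self, offset_s: float, segment_id: int | None = None) -> "Event":
        return Event(
            kind=self.kind,
            segment_id=self.segment_id if segment_id is None else segment_id,
            start_s=self.start_s + offset_s,
            end_s=self.end_s + offset_s,
            peak_value=self.peak_value,
            peak_time_s=self.peak_time_s + offset_s,
        )
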