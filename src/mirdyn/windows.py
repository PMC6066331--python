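"""Time-window grid used throughout the pipeline.

Embryo collections are binned into contiguous windows on the hours-after-egg-laying
(hAEL) axis.  The study grid is eight windows: 2 h windows from 0-12 hAEL and 6 h
windows covering 12-18 and 18-24 hAEL.  Windows are labelled ``"h00-02"`` ...
``"h18-24"`` so that tables round-trip through TSV with self-describing columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "TimeWindow",
    "DEFAULT_WINDOW_BOUNDS",
    "default_windows",
    "make_windows",
    "format_window",
    "parse_window",
    "windows_from_labels",
]

#: 2 h windows 0-12 hAEL, then 6 h windows to 24 hAEL.
DEFAULT_WINDOW_BOUNDS: tuple[tuple[float, float], ...] = (
    (0, 2), (2, 4), (4, 6), (6, 8), (8, 10), (10, 12), (12, 18), (18, 24),
)

_LABEL_RE = re.compile(r"^h(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class TimeWindow:
    """A half-open collection window [start, end) in hours AEL."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"window end must exceed start, got [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def width(self) -> float:
        return self.end - self.start

    @property
    def label(self) -> str:
        return format_window(self.start, self.end)


def format_window(start: float, end: float) -> str:
    def fmt(x: float) -> str:
        if float(x).is_integer():
            return f"{int(x):02d}"
        return f"{x:g}"

    return f"h{fmt(start)}-{fmt(end)}"


def parse_window(label: str) -> TimeWindow:
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse window label {label!r} (expected e.g. 'h00-02')")
    return TimeWindow(float(m.group(1)), float(m.group(2)))


def make_windows(bounds: Sequence[tuple[float, float]]) -> list[TimeWindow]:
    """Validate and build an ordered, non-overlapping window grid."""
    wins = [TimeWindow(float(s), float(e)) for s, e in bounds]
    for prev, cur in zip(wins, wins[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"windows must be ordered and non-overlapping: {prev.label} then {cur.label}"
            )
    if not wins:
        raise ValueError("window grid is empty")
    return wins


def default_windows() -> list[TimeWindow]:
    return make_windows(DEFAULT_WINDOW_BOUNDS)


def windows_from_labels(labels: Sequence[str]) -> list[TimeWindow]:
    return make_windows([(w.start, w.end) for w in map(parse_window, labels)])
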