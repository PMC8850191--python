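"""Idealized single-channel event lists.

An :class:`EventList` is the common currency between the gating simulator,
the idealizer and the dwell-time statistics: a strictly alternating sequence
of open/closed sojourns with durations in milliseconds, a dead time (the
shortest resolvable event) and the total record length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Event", "EventList", "apply_dead_time"]

OPEN = "open"
CLOSED = "closed"


@dataclass
class Event:
    state: str  # "open" | "closed"
    duration: float  # ms
    mean_amplitude: float = 0.0  # pA
    #: time within the event spent at >= 2x the unitary level (ms); nonzero
    #: only for idealized records from multi-channel patches
    stacked_time: float = 0.0

    def __post_init__(self) -> None:
        if self.state not in (OPEN, CLOSED):
            raise ValueError(f"state must be 'open' or 'closed', got {self.state!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class EventList:
    """Alternating open/closed dwell sequence.

    ``first_partial``/``last_partial`` flag edge events whose true duration
    is censored by the start/end of the record; dwell statistics exclude
    them by default.
    """

    events: list[Event]
    dead_time: float = 0.0  # us
    total_duration: float = 0.0  # s
    first_partial: bool = False
    last_partial: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if a.state == b.state:
                raise ValueError("event states must strictly alternate")
        if self.total_duration and sum(e.duration for e in self.events) > (
            self.total_duration * 1e3 + 1e-6
        ):
            raise ValueError("summed event durations exceed total_duration")

    def __len__(self) -> int:
        return len(self.events)

    def durations(self, state: str, include_partial: bool = False) -> np.ndarray:
        """Dwell durations (ms) of one state class.

        Censored first/last events are excluded unless ``include_partial``.
        """
        evs = self.events
        skip_first = self.first_partial and not include_partial
        skip_last = self.last_partial and not include_partial
        lo = 1 if skip_first else 0
        hi = len(evs) - 1 if skip_last else len(evs)
        return np.array(
            [e.duration for e in evs[lo:hi] if e.state == state], dtype=float
        )

    def open_time(self) -> float:
        """Total open time (ms), edge events included."""
        return float(sum(e.duration for e in self.events if e.state == OPEN))

    def reversed(self) -> "EventList":
        return replace(
            self,
            events=list(reversed([replace(e) for e in self.events])),
            first_partial=self.last_partial,
            last_partial=self.first_partial,
        )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [e.state for e in self.events],
                "duration_ms": [e.duration for e in self.events],
                "amplitude_pA": [e.mean_amplitude for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def with_dead_time(self, dead_time: float) -> "EventList":
        """Event list as seen at a finite time resolution: see
        :func:`apply_dead_time`."""
        return apply_dead_time(self, dead_time)

    @classmethod
    def from_csv(
        cls, path: str | Path, dead_time: float = 0.0, total_duration: float = 0.0
    ) -> "EventList":
        df = pd.read_csv(path)
        events = [
            Event(state=row.state, duration=row.duration_ms,
                  mean_amplitude=row.amplitude_pA)
            for row in df.itertuples()
        ]
        if not total_duration:
            total_duration = sum(e.duration for e in events) / 1e3
        return cls(events=events, dead_time=dead_time, total_duration=total_duration)


def apply_dead_time(events: EventList, dead_time: float) -> EventList:
    """Merge interior events shorter than ``dead_time`` (us) into the
    flanking state.

    This is what a finite-resolution recording system does to a true gating
    sequence: a sojourn too brief to resolve disappears and its neighbours
    (which share the opposite state) coalesce.  The shortest sub-resolution
    event is removed first and the scan repeats, so the operation is
    idempotent at the same dead time.
    """
    dt_ms = dead_time * 1e-3
    runs: list[list] = [[e.state, e.duration, e.mean_amplitude,
                         e.stacked_time] for e in events.events]
    while len(runs) >= 3:
        interior = [
            (r[1], i) for i, r in enumerate(runs)
            if 0 < i < len(runs) - 1 and r[1] < dt_ms
        ]
        if not interior:
            break
        _, i = min(interior)
        prev, mid, nxt = runs[i - 1], runs[i], runs[i + 1]
        total = prev[1] + mid[1] + nxt[1]
        amp = (
            (prev[2] * prev[1] + mid[2] * mid[1] + nxt[2] * nxt[1]) / total
            if total > 0 else prev[2]
        )
        runs[i - 1: i + 2] = [[prev[0], total, amp, prev[3] + nxt[3]]]
    return EventList(
        events=[Event(state=s, duration=d, mean_amplitude=a, stacked_time=st)
                for s, d, a, st in runs],
        dead_time=dead_time,
        total_duration=events.total_duration,
        first_partial=events.first_partial,
        last_partial=events.last_partial,
        meta=dict(events.meta),
    )
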