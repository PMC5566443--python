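"""Classification of dyadic calls into self-contained and reactive modes.

In the merged stream of a pair's calls, each call after the first is
classified by its immediately preceding event:

* same individual  -> self-contained (``f-f`` for a female call, ``m-m`` male),
* the partner      -> reactive (``m-f`` female call after a male call,
  ``f-m`` male call after a female call).

The inter-event interval ``tau`` is the time to that defining predecessor.
The first merged event has no predecessor and stays unclassified.  Ties are
resolved by input order, so an equal-time partner predecessor yields a
reactive interval of exactly 0 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .events_io import ActivityMask, CallEvent, DyadRecording, StructureError

__all__ = [
    "MODES",
    "ClassifiedCall",
    "IntervalSet",
    "IntervalSummary",
    "classify_calls",
    "intervals_by_mode",
    "interval_summary",
]

#: the four calling modes: (role of the caller, role of the predecessor)
MODES = ("f-f", "m-m", "m-f", "f-m")

_SELF_MODE = {"female": "f-f", "male": "m-m"}
# reactive labels name predecessor-caller: a female call after a male is "m-f"
_REACTIVE_MODE = {"female": "m-f", "male": "f-m"}


class ClassifiedCall(NamedTuple):
    event: CallEvent
    mode: str  # one of MODES or "unclassified"
    tau: float | None  # seconds to the defining predecessor


@dataclass
class IntervalSet:
    """The inter-event intervals of one calling mode for one recording."""

    mode: str
    taus: np.ndarray
    pair_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        if self.taus.ndim != 1:
            raise ValueError("taus must be one-dimensional")
        if self.taus.size and not np.all(np.isfinite(self.taus)):
            raise ValueError("all intervals must be finite")
        if self.taus.size and np.any(self.taus < 0):
            raise ValueError("intervals must be non-negative")

    @property
    def n(self) -> int:
        return int(self.taus.size)


class IntervalSummary(NamedTuple):
    """Sample summary of an interval multiset (sigma absent for n < 2)."""

    n: int
    min_tau: float
    max_tau: float
    mean_tau: float
    std_tau: float | None


def classify_calls(recording: DyadRecording) -> list[ClassifiedCall]:
    """Assign each call of the merged stream its mode and interval.

    The first merged event is unclassified.  For every later event the
    immediately preceding merged event decides the mode, and ``tau`` is the
    (non-negative) time difference to it.
    """
    events = recording.events
    if not events:
        raise StructureError("no events")
    out: list[ClassifiedCall] = [ClassifiedCall(events[0], "unclassified", None)]
    for prev, cur in zip(events, events[1:]):
        role = recording.role_of(cur.individual)
        if prev.individual == cur.individual:
            mode = _SELF_MODE[role]
        else:
            mode = _REACTIVE_MODE[role]
        out.append(ClassifiedCall(cur, mode, cur.time - prev.time))
    return out


def intervals_by_mode(
    classified: Sequence[ClassifiedCall],
    mode: str,
    mask: ActivityMask | None = None,
    pair_id: str = "",
    condition: str = "",
) -> IntervalSet:
    """Collect the intervals of one mode, dropping gap-crossing intervals.

    An interval is excluded when its two generating events do not lie in one
    common mask window (the pair straddles a recording gap such as night).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    taus = []
    for call in classified:
        if call.mode != mode:
            continue
        if mask is not None and not mask.same_window(call.event.time - call.tau, call.event.time):
            continue
        taus.append(call.tau)
    return IntervalSet(mode=mode, taus=np.array(taus, dtype=float), pair_id=pair_id, condition=condition)


def interval_summary(intervals: IntervalSet) -> IntervalSummary:
    """Sample min, max, mean and (n-1)-denominator SD of the intervals."""
    taus = intervals.taus
    if taus.size == 0:
        raise ValueError("no intervals")
    std = float(np.std(taus, ddof=1)) if taus.size >= 2 else None
    return IntervalSummary(
        n=int(taus.size),
        min_tau=float(taus.min()),
        max_tau=float(taus.max()),
        mean_tau=float(taus.mean()),
        std_tau=std,
    )
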