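"""Reading, validating, masking and writing dyadic vocal-event tables.

The portable interchange format is a delimited text table (comma by default,
tab accepted) with a header row and columns::

    pair, individual, sex, time_s, label, condition

``time_s`` is seconds from the recording origin (t0 = 0 at the start of the
first observation window).  The observation schedule — the light-cycle windows
during which the animals are actually recorded — is an :class:`ActivityMask`:
night is represented as *absent* windows rather than deleted time, so that
downstream interval computations can recognize and drop gap-crossing
inter-event intervals.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CallEvent",
    "ActivityMask",
    "DyadRecording",
    "FormatError",
    "StructureError",
    "read_event_table",
    "write_event_table",
    "read_mask",
    "write_mask",
    "apply_activity_mask",
]

#: column order of the canonical event table
TABLE_COLUMNS = ("pair", "individual", "sex", "time_s", "label", "condition")

#: decimal places kept when serializing times (sub-millisecond; telemetric
#: onset annotations carry no more)
TIME_DECIMALS = 6


class FormatError(ValueError):
    """The file cannot be parsed as an event table."""


class StructureError(ValueError):
    """The table parses but violates the dyadic-recording contract."""


class CallEvent(NamedTuple):
    """One time-stamped vocalization by one identified individual."""

    individual: str
    time: float
    label: str | None = None


@dataclass(frozen=True)
class ActivityMask:
    """Ordered, disjoint half-open observation windows ``[start, end)`` in seconds."""

    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.windows:
            if not (np.isfinite(start) and np.isfinite(end) and start < end):
                raise StructureError(f"invalid mask window [{start}, {end})")
            if start < prev_end:
                raise StructureError("mask windows must be sorted and disjoint")
            prev_end = end

    @property
    def total_span(self) -> float:
        return float(sum(end - start for start, end in self.windows))

    @property
    def start(self) -> float:
        return self.windows[0][0]

    @property
    def end(self) -> float:
        return self.windows[-1][1]

    def contains(self, times: np.ndarray | float) -> np.ndarray:
        """Boolean mask: does each time fall inside some window?"""
        t = np.asarray(times, dtype=float)
        inside = np.zeros(t.shape, dtype=bool)
        for start, end in self.windows:
            inside |= (t >= start) & (t < end)
        return inside

    def window_index(self, times: np.ndarray | float) -> np.ndarray:
        """Index of the window containing each time, -1 outside all windows."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.full(t.shape, -1, dtype=int)
        for i, (start, end) in enumerate(self.windows):
            idx[(t >= start) & (t < end)] = i
        return idx

    def same_window(self, t_a: float, t_b: float) -> bool:
        """True iff both times lie in one common window (no gap between them)."""
        ia, ib = self.window_index([t_a, t_b])
        return ia >= 0 and ia == ib

    @classmethod
    def covering(cls, duration: float) -> "ActivityMask":
        """A single all-covering window ``[0, duration)``."""
        return cls(windows=((0.0, float(duration)),))


@dataclass
class DyadRecording:
    """The merged, time-ordered event streams of one pair in a masked window.

    ``roles`` maps each of the exactly-two individual identifiers to
    ``"female"`` or ``"male"``.  Events are sorted by time; ties preserve
    input order (needed so zero reactive intervals remain well-defined).
    """

    pair_id: str
    roles: dict[str, str]
    events: list[CallEvent]
    mask: ActivityMask
    condition: str = "baseline"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.roles) != 2:
            raise StructureError(
                f"a dyad needs exactly two individuals, got {sorted(self.roles)}"
            )
        if set(self.roles.values()) != {"female", "male"}:
            raise StructureError(
                f"roles must be one female and one male, got {self.roles}"
            )
        if not self.events:
            raise StructureError("no events")
        times = np.array([e.time for e in self.events], dtype=float)
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise StructureError("event times must be finite and non-negative")
        if np.any(np.diff(times) < 0):
            raise StructureError("events must be sorted by time")
        extra = {e.individual for e in self.events} - set(self.roles)
        if extra:
            raise StructureError(f"events from undeclared individuals: {sorted(extra)}")
        if not self.mask.contains(times).all():
            raise StructureError("every event must lie inside a mask window")

    @property
    def individuals(self) -> tuple[str, str]:
        return tuple(self.roles)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def times_of(self, individual: str) -> np.ndarray:
        return np.array(
            [e.time for e in self.events if e.individual == individual], dtype=float
        )

    def role_of(self, individual: str) -> str:
        return self.roles[individual]

    def to_frame(self) -> pd.DataFrame:
        sex_short = {"female": "f", "male": "m"}
        return pd.DataFrame(
            {
                "pair": self.pair_id,
                "individual": [e.individual for e in self.events],
                "sex": [sex_short[self.roles[e.individual]] for e in self.events],
                "time_s": [e.time for e in self.events],
                "label": [e.label if e.label is not None else "" for e in self.events],
                "condition": self.condition,
            },
            columns=list(TABLE_COLUMNS),
        )


_SEX_TO_ROLE = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}


def _roles_from_frame(df: pd.DataFrame) -> dict[str, str]:
    individuals = list(dict.fromkeys(df["individual"]))  # first-seen order
    if len(individuals) < 2:
        raise StructureError(
            f"a dyadic table needs two distinct individuals, found {individuals}"
        )
    if len(individuals) > 2:
        raise StructureError(
            "more than two individuals in the table; extras: "
            f"{individuals[2:]}"
        )
    roles: dict[str, str] = {}
    for ind in individuals:
        sexes = set(df.loc[df["individual"] == ind, "sex"].astype(str).str.lower())
        if len(sexes) != 1:
            raise StructureError(f"individual {ind!r} has inconsistent sex labels")
        sex = sexes.pop()
        if sex not in _SEX_TO_ROLE:
            raise FormatError(f"unrecognized sex label {sex!r} for {ind!r}")
        roles[ind] = _SEX_TO_ROLE[sex]
    if set(roles.values()) != {"female", "male"}:
        raise StructureError(f"need one female and one male, got {roles}")
    return roles


def read_event_table(
    path: str | Path | io.TextIOBase,
    mask: ActivityMask | None = None,
    format_spec: dict[str, str] | None = None,
) -> DyadRecording:
    """Read a delimited dyadic event table into a validated :class:`DyadRecording`.

    Parameters
    ----------
    path
        File path or open text handle; comma- or tab-delimited, with header.
    mask
        Observation windows.  Rows outside the windows are dropped (count
        logged).  When omitted, a single window covering all events is used.
    format_spec
        Optional mapping from canonical column names (``individual``,
        ``time_s``, ...) to the names actually present in the file.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise StructureError("no events") from None
    except csv.Error as exc:  # the sniffer cannot see a delimiter in an empty file
        raise StructureError(f"no events ({exc})") from None
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(str(exc)) from exc
    if format_spec:
        df = df.rename(columns={v: k for k, v in format_spec.items()})
    missing = {"individual", "time_s"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    if df.empty:
        raise StructureError("no events")
    for col, default in (("pair", "pair"), ("sex", ""), ("label", ""), ("condition", "baseline")):
        if col not in df.columns:
            df[col] = default
    try:
        times = df["time_s"].astype(float)
    except ValueError as exc:
        raise FormatError(f"unparseable time_s values: {exc}") from exc
    df = df.assign(time_s=times)
    if df["sex"].fillna("").eq("").all():
        raise FormatError("missing required columns: ['sex']")

    pair_ids = set(df["pair"].astype(str))
    if len(pair_ids) != 1:
        raise StructureError(f"expected one pair per table, found {sorted(pair_ids)}")
    conditions = set(df["condition"].astype(str))
    if len(conditions) != 1:
        raise StructureError(f"expected one condition per table, found {sorted(conditions)}")

    roles = _roles_from_frame(df)
    if mask is None:
        mask = ActivityMask.covering(float(times.max()) + 1.0)
    inside = mask.contains(times.to_numpy())
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("read_event_table: dropped %d rows outside mask windows", n_dropped)
    df = df.loc[inside]
    if df.empty:
        raise StructureError("no events inside the mask windows")
    df = df.sort_values("time_s", kind="stable")

    events = [
        CallEvent(
            individual=str(row.individual),
            time=float(row.time_s),
            label=(str(row.label) or None) if not pd.isna(row.label) else None,
        )
        for row in df.itertuples()
    ]
    return DyadRecording(
        pair_id=str(df["pair"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        roles=roles,
        events=events,
        mask=mask,
    )


def write_event_table(recording: DyadRecording, path: str | Path, sep: str = ",") -> Path:
    """Serialize a recording; re-reading reproduces events, roles and times.

    Times are written with :data:`TIME_DECIMALS` decimals; tie order among
    equal timestamps is preserved (stable round-trip).
    """
    if not recording.events:
        raise StructureError("refusing to serialize a recording with no events")
    df = recording.to_frame()
    df["time_s"] = df["time_s"].map(lambda t: f"{t:.{TIME_DECIMALS}f}")
    path = Path(path)
    try:
        df.to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise IOError(f"cannot write event table to {path}: {exc}") from exc
    return path


def read_mask(path: str | Path) -> ActivityMask:
    """Read an activity mask from a small YAML/JSON config.

    Accepts either ``{"windows": [[start, end], ...]}`` or a bare list of
    ``[start, end]`` pairs, in seconds.
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if isinstance(payload, dict):
        payload = payload.get("windows")
    if not isinstance(payload, Sequence) or not payload:
        raise FormatError(f"mask file {path} must contain a list of [start, end] windows")
    windows = tuple((float(a), float(b)) for a, b in payload)
    return ActivityMask(windows=windows)


def write_mask(mask: ActivityMask, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump({"windows": [list(w) for w in mask.windows]}, fh)
    return path


def apply_activity_mask(recording: DyadRecording, mask: ActivityMask) -> DyadRecording:
    """Restrict a recording to events inside the mask's windows.

    A pure filter: the surviving event set is a subset of the original and the
    operation is idempotent.  The mask is attached to the result so that
    interval extraction can drop intervals that straddle a gap (e.g. night).
    """
    if mask.total_span <= 0:
        raise StructureError("mask with zero total span")
    kept = [e for e in recording.events if bool(mask.contains(e.time))]
    n_dropped = len(recording.events) - len(kept)
    if n_dropped:
        logger.info(
            "apply_activity_mask: dropped %d of %d events outside windows",
            n_dropped,
            len(recording.events),
        )
    if not kept:
        raise StructureError("no events remain inside the mask windows")
    return replace(recording, events=kept, mask=mask)
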