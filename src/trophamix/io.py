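"""Reading, validating and writing trophallactic interaction schedules.

The canonical on-disk dialect is a UTF-8 CSV with header
``colony_id,time_s,donor,recipient,volume,ambiguous``.  Food entering the
colony from the external source is recorded as an event whose donor is the
reserved label ``SOURCE``; the recipient of such an event is a forager
loading food at the source.  All other events are ant-to-ant trophallaxis.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Reserved donor label for source-feeding events.
SOURCE = "SOURCE"

REQUIRED_COLUMNS = ("colony_id", "time_s", "donor", "recipient", "volume")
CANONICAL_COLUMNS = REQUIRED_COLUMNS + ("ambiguous",)

#: Accepted aliases for canonical column names (spreadsheet imports vary).
_COLUMN_ALIASES = {
    "colony": "colony_id",
    "time": "time_s",
    "interaction_time": "time_s",
    "giver": "donor",
    "receiver": "recipient",
    "size": "volume",
    "interaction_size": "volume",
}


class ScheduleFormatError(ValueError):
    """A schedule table is structurally malformed (e.g. missing column)."""


class ScheduleValidationError(ValueError):
    """A schedule row violates an invariant (negative volume, self-transfer...)."""


@dataclass(frozen=True)
class InteractionEvent:
    """One trophallactic or source-feeding event.

    Parameters
    ----------
    colony_id : str
        Label of the colony the event belongs to.
    time : float
        Seconds from experiment start (non-negative).
    donor : str
        Ant label, or :data:`SOURCE` for a forager loading at the food source.
    recipient : str
        Ant label; never :data:`SOURCE`.
    volume : float
        Transferred amount in crop units (non-negative).
    ambiguous : bool
        Flags events whose direction/volume fell below detection error.
    """

    colony_id: str
    time: float
    donor: str
    recipient: str
    volume: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ScheduleValidationError(
                f"donor equals recipient ({self.donor!r}) at t={self.time}"
            )
        if self.recipient == SOURCE:
            raise ScheduleValidationError("recipient may not be SOURCE")
        if self.volume < 0:
            raise ScheduleValidationError(f"negative volume {self.volume}")
        if self.time < 0:
            raise ScheduleValidationError(f"negative time {self.time}")

    @property
    def is_source_event(self) -> bool:
        return self.donor == SOURCE


@dataclass
class ColonySchedule:
    """A validated, time-ordered interaction schedule for one colony.

    ``ants`` covers every ant label appearing in any event; ``foragers`` is
    the subset that loads food at the source (all food enters the colony
    through them, and food "types" are indexed by forager identity).
    Ties in time are broken by original file order (stable sort), giving a
    deterministic total order indexed by interaction number.
    """

    colony_id: str
    events: list[InteractionEvent]
    foragers: list[str] = field(default_factory=list)
    capacities: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        self.validate()

    @property
    def ants(self) -> list[str]:
        """All ant labels, foragers first, in first-appearance order."""
        seen: dict[str, None] = {f: None for f in self.foragers}
        for ev in self.events:
            if ev.donor != SOURCE:
                seen.setdefault(ev.donor, None)
            seen.setdefault(ev.recipient, None)
        return list(seen)

    def validate(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleValidationError("events not sorted by time")
        if SOURCE in self.foragers:
            raise ScheduleValidationError("SOURCE cannot be a forager")

    def source_events(self) -> list[InteractionEvent]:
        return [e for e in self.events if e.is_source_event]

    def trophallaxis_events(self) -> list[InteractionEvent]:
        return [e for e in self.events if not e.is_source_event]

    def with_foragers(self, foragers: Iterable[str]) -> "ColonySchedule":
        out = replace(self)
        out.foragers = list(foragers)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "colony_id": [e.colony_id for e in self.events],
                "time_s": [e.time for e in self.events],
                "donor": [e.donor for e in self.events],
                "recipient": [e.recipient for e in self.events],
                "volume": [e.volume for e in self.events],
                "ambiguous": [e.ambiguous for e in self.events],
            }
        )


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {
        c: _COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower())
        for c in df.columns
    }
    return df.rename(columns=renames)


def _events_from_frame(df: pd.DataFrame) -> list[InteractionEvent]:
    events = []
    for row in df.itertuples(index=True):
        rownum = row.Index + 2  # 1-based plus header line
        try:
            events.append(
                InteractionEvent(
                    colony_id=str(row.colony_id),
                    time=float(row.time_s),
                    donor=str(row.donor),
                    recipient=str(row.recipient),
                    volume=float(row.volume),
                    ambiguous=bool(getattr(row, "ambiguous", False)),
                )
            )
        except ScheduleValidationError as exc:
            raise ScheduleValidationError(f"row {rownum}: {exc}") from exc
    return events


def read_interactions(
    source: str | Path | _stdio.TextIOBase,
) -> dict[str, ColonySchedule]:
    """Read a canonical-dialect CSV into one schedule per colony.

    Returns a mapping ``colony_id -> ColonySchedule``.  Foragers are
    identified from SOURCE events where present (see
    :func:`identify_foragers`); schedules without SOURCE events are returned
    with an empty forager set that must be supplied by the caller.
    """
    df = pd.read_csv(
        source,
        dtype={"colony_id": str, "donor": str, "recipient": str},
        float_precision="round_trip",
    )
    df = _canonicalize_columns(df)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ScheduleFormatError(f"missing required column {col!r}")
    if "ambiguous" not in df.columns:
        df["ambiguous"] = False
    df["ambiguous"] = df["ambiguous"].fillna(False).astype(bool)

    schedules = {}
    for colony_id, sub in df.groupby("colony_id", sort=False):
        events = _events_from_frame(sub.reset_index(drop=True))
        sched = ColonySchedule(colony_id=str(colony_id), events=events)
        try:
            sched.foragers = sorted(identify_foragers(sched))
        except ScheduleValidationError:
            sched.foragers = []
        schedules[str(colony_id)] = sched
    return schedules


def read_single_colony(source: str | Path | _stdio.TextIOBase) -> ColonySchedule:
    """Read a CSV expected to contain exactly one colony."""
    schedules = read_interactions(source)
    if len(schedules) != 1:
        raise ScheduleFormatError(
            f"expected a single colony, found {sorted(schedules)}"
        )
    return next(iter(schedules.values()))


def write_interactions(
    schedules: ColonySchedule | Sequence[ColonySchedule] | Mapping[str, ColonySchedule],
    target: str | Path | _stdio.TextIOBase,
) -> None:
    """Write schedules in the canonical dialect (round-trips bit-exactly)."""
    if isinstance(schedules, ColonySchedule):
        schedules = [schedules]
    elif isinstance(schedules, Mapping):
        schedules = list(schedules.values())
    frame = pd.concat([s.to_frame() for s in schedules], ignore_index=True)
    # %.17g guarantees float round-tripping for the canonical dialect
    frame.to_csv(target, index=False, float_format="%.17g")


def import_workbook(path: str | Path) -> dict[str, ColonySchedule]:
    """Import an S1-Data-style spreadsheet: one sheet per colony.

    Each sheet must carry the required columns (aliases such as ``time`` or
    ``interaction_size`` are accepted); ``colony_id`` defaults to the sheet
    name when absent.  The importer surfaces exactly what the workbook
    contains: if no SOURCE rows are present the forager set is left empty
    for the caller to supply.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    schedules = {}
    for name, df in sheets.items():
        df = _canonicalize_columns(df)
        if "colony_id" not in df.columns:
            df["colony_id"] = str(name)
        if "ambiguous" not in df.columns:
            df["ambiguous"] = False
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ScheduleFormatError(
                    f"sheet {name!r}: missing required column {col!r}"
                )
        df = df.astype({"colony_id": str, "donor": str, "recipient": str})
        events = _events_from_frame(df.reset_index(drop=True))
        sched = ColonySchedule(colony_id=str(name), events=events)
        try:
            sched.foragers = sorted(identify_foragers(sched))
        except ScheduleValidationError:
            sched.foragers = []
        schedules[str(name)] = sched
    return schedules


def write_capacities(capacities: Mapping[str, float], target: str | Path) -> None:
    """Write an ant -> crop capacity table (columns ``ant,capacity``)."""
    pd.DataFrame(
        {"ant": list(capacities), "capacity": list(capacities.values())}
    ).to_csv(target, index=False, float_format="%.17g")


def read_capacities(source: str | Path) -> dict[str, float]:
    """Read an ``ant,capacity`` table written by :func:`write_capacities`."""
    df = pd.read_csv(source, dtype={"ant": str}, float_precision="round_trip")
    for col in ("ant", "capacity"):
        if col not in df.columns:
            raise ScheduleFormatError(f"missing required column {col!r}")
    return dict(zip(df["ant"], df["capacity"].astype(float)))


def identify_foragers(
    schedule: ColonySchedule, override: Iterable[str] | None = None
) -> set[str]:
    """Identify the forager subset of a schedule.

    Foragers are the ants that load food at the external source, i.e. the
    recipients of SOURCE events.  An explicit ``override`` takes precedence
    (useful when the schedule omits source-feeding events).  The result is
    also stored on ``schedule.foragers``.
    """
    if override is not None:
        foragers = set(override)
    else:
        foragers = {e.recipient for e in schedule.events if e.is_source_event}
    if not foragers:
        raise ScheduleValidationError("no foragers identifiable")
    schedule.foragers = sorted(foragers)
    return foragers


def estimate_capacities(trace) -> tuple[dict[str, float], set[str]]:
    """Estimate per-ant crop capacities from a provenance trace.

    The capacity of an ant is taken as the maximum crop load it was ever
    observed to hold — a lower bound on the true physiological capacity,
    and the only schedule-derivable proxy.  Ants that never held food have
    undefined capacity and are returned in the flagged set instead.

    Returns
    -------
    capacities : dict
        ant label -> max observed load (only ants that ever held food).
    undefined : set
        ants that never held food.
    """
    loads = trace.loads()  # (n_steps, n_ants)
    peak = loads.max(axis=0)
    capacities = {}
    undefined = set()
    for ant, mx in zip(trace.ants, peak):
        if mx > 0:
            capacities[ant] = float(mx)
        else:
            undefined.add(ant)
    return capacities, undefined
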