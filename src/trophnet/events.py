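"""Trophallaxis event logs and individual rosters.

The observational unit is a single mouth-to-mouth nectar transfer
(trophallaxis) between two tagged honey bees: one donor, one receiver,
a start time (seconds from the start of filming) and a duration in
seconds.  Alongside the event log sits a roster of individuals with
their age in days (or unknown), their role (worker or queen) and any
observed hygienic acts — uncapping a brood cell or removing a dead
pupa — each with a timestamp on the same clock as the events.  Acts
performed during the manual observation period before filming carry
non-positive timestamps.

This module reads and writes the delimited-text formats for both
tables, validates them with line-numbered errors, applies the
short-interaction filter (exchanges under 2 s rarely involve nectar
transfer and are dropped), and codes each individual's hygienic status:
an individual that performed a hygienic act counts as hygienic unless
every one of its social interactions took place strictly before its
earliest hygienic act.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

TASKS = frozenset({"uncap", "remove"})
ROLES = frozenset({"worker", "queen"})

EVENT_COLUMNS = ("colony_id", "donor_id", "receiver_id", "start_time_s", "duration_s")
ROSTER_COLUMNS = ("colony_id", "id", "age_days", "role")
ACT_COLUMNS = ("colony_id", "id", "task", "act_time_s")

#: Exchanges shorter than this (seconds) are considered too brief for
#: actual nectar transfer and are excluded; the boundary value is kept.
MIN_DURATION_S = 2.0


class EventLogError(ValueError):
    """Base class for event-log / roster format problems."""


class SchemaError(EventLogError):
    """The header row does not name the required columns."""


class ParseError(EventLogError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class ValidationError(EventLogError):
    """A parsed value violates a semantic invariant."""


@dataclass(frozen=True)
class TrophallaxisEvent:
    """One directed, timed, weighted nectar exchange (donor -> receiver)."""

    donor_id: str
    receiver_id: str
    start_time: float
    duration: float
    colony_id: str = ""

    def __post_init__(self):
        if self.donor_id == self.receiver_id:
            raise ValidationError(
                f"donor and receiver are the same individual ({self.donor_id!r})"
            )
        if not self.duration > 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        if self.start_time < 0:
            raise ValidationError(
                f"start_time must be non-negative, got {self.start_time}"
            )

    def participants(self) -> tuple[str, str]:
        return (self.donor_id, self.receiver_id)


@dataclass(frozen=True)
class HygienicAct:
    """A single observed hygienic act (uncap or remove) with its timestamp.

    ``act_time <= 0`` marks acts observed during the manual watch that
    preceded filming.
    """

    task: str
    act_time: float

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValidationError(
                f"task must be one of {sorted(TASKS)}, got {self.task!r}"
            )


@dataclass(frozen=True)
class IndividualRecord:
    """An individual's identity, age, role and hygienic-act history."""

    id: str
    age_days: int | None = None
    role: str = "worker"
    hygienic_acts: tuple[HygienicAct, ...] = ()
    colony_id: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(
                f"role must be one of {sorted(ROLES)}, got {self.role!r}"
            )

    def with_acts(self, acts: Iterable[HygienicAct]) -> "IndividualRecord":
        return replace(self, hygienic_acts=tuple(acts))


# ---------------------------------------------------------------------------
# event-log I/O
# ---------------------------------------------------------------------------


def _check_header(header: Sequence[str] | None, required: Sequence[str], what: str):
    if header is None:
        raise SchemaError(f"{what}: file is empty, expected a header row")
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{what}: header is missing column(s) {missing}")


def _parse_float(raw: str, column: str, line_no: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(line_no, f"non-numeric {column} {raw!r}") from None


def read_event_log(path: str | Path, delimiter: str = ",") -> list[TrophallaxisEvent]:
    """Read a trophallaxis event log, preserving row order.

    The file must have a header naming the five columns
    ``colony_id,donor_id,receiver_id,start_time_s,duration_s``.  Rows
    that cannot be parsed or that violate event invariants raise errors
    carrying the offending 1-based line number.
    """
    events: list[TrophallaxisEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        _check_header(header, EVENT_COLUMNS, str(path))
        col = {name: header.index(name) for name in EVENT_COLUMNS}
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise ParseError(line_no, f"expected {len(header)} fields, got {len(row)}")
            try:
                event = TrophallaxisEvent(
                    donor_id=row[col["donor_id"]].strip(),
                    receiver_id=row[col["receiver_id"]].strip(),
                    start_time=_parse_float(row[col["start_time_s"]], "start_time_s", line_no),
                    duration=_parse_float(row[col["duration_s"]], "duration_s", line_no),
                    colony_id=row[col["colony_id"]].strip(),
                )
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from None
            events.append(event)
    return events


def write_event_log(events: Iterable[TrophallaxisEvent], path: str | Path,
                    delimiter: str = ",") -> None:
    """Write an event log in the same format :func:`read_event_log` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow([e.colony_id, e.donor_id, e.receiver_id,
                             repr(e.start_time), repr(e.duration)])


# ---------------------------------------------------------------------------
# roster I/O
# ---------------------------------------------------------------------------


def read_roster(roster_path: str | Path, acts_path: str | Path | None = None,
                delimiter: str = ",") -> list[IndividualRecord]:
    """Read a roster and (optionally) a long-format hygienic-act table.

    Age may be blank or ``NA`` for individuals of unknown age.  At most
    one queen is allowed per colony.  Every act row must reference an id
    present in the roster.
    """
    records: dict[tuple[str, str], IndividualRecord] = {}
    queens: set[str] = set()
    with open(roster_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        _check_header(header, ROSTER_COLUMNS, str(roster_path))
        col = {name: header.index(name) for name in ROSTER_COLUMNS}
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            raw_age = row[col["age_days"]].strip()
            if raw_age in ("", "NA", "na", "unknown"):
                age: int | None = None
            else:
                try:
                    age = int(float(raw_age))
                except ValueError:
                    raise ParseError(line_no, f"non-numeric age_days {raw_age!r}") from None
            try:
                rec = IndividualRecord(
                    id=row[col["id"]].strip(),
                    age_days=age,
                    role=row[col["role"]].strip(),
                    colony_id=row[col["colony_id"]].strip(),
                )
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from None
            key = (rec.colony_id, rec.id)
            if key in records:
                raise ValidationError(f"line {line_no}: duplicate id {rec.id!r}")
            if rec.role == "queen":
                if rec.colony_id in queens:
                    raise ValidationError(
                        f"line {line_no}: more than one queen in colony {rec.colony_id!r}"
                    )
                queens.add(rec.colony_id)
            records[key] = rec

    if acts_path is not None:
        acts: dict[tuple[str, str], list[HygienicAct]] = {}
        with open(acts_path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=delimiter)
            header = next(reader, None)
            _check_header(header, ACT_COLUMNS, str(acts_path))
            col = {name: header.index(name) for name in ACT_COLUMNS}
            for line_no, row in enumerate(reader, start=2):
                if not row or all(not cell.strip() for cell in row):
                    continue
                key = (row[col["colony_id"]].strip(), row[col["id"]].strip())
                if key not in records:
                    raise ValidationError(
                        f"line {line_no}: act references unknown individual {key[1]!r}"
                    )
                try:
                    act = HygienicAct(
                        task=row[col["task"]].strip(),
                        act_time=_parse_float(row[col["act_time_s"]], "act_time_s", line_no),
                    )
                except ValidationError as exc:
                    raise ValidationError(f"line {line_no}: {exc}") from None
                acts.setdefault(key, []).append(act)
        for key, act_list in acts.items():
            records[key] = records[key].with_acts(act_list)

    return list(records.values())


def write_roster(records: Iterable[IndividualRecord], roster_path: str | Path,
                 acts_path: str | Path | None = None, delimiter: str = ",") -> None:
    records = list(records)
    with open(roster_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ROSTER_COLUMNS)
        for r in records:
            age = "" if r.age_days is None else r.age_days
            writer.writerow([r.colony_id, r.id, age, r.role])
    if acts_path is not None:
        with open(acts_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(ACT_COLUMNS)
            for r in records:
                for act in r.hygienic_acts:
                    writer.writerow([r.colony_id, r.id, act.task, repr(act.act_time)])


# ---------------------------------------------------------------------------
# filtering and hygienic coding
# ---------------------------------------------------------------------------


def filter_short_events(events: Sequence[TrophallaxisEvent],
                        min_duration: float = MIN_DURATION_S) -> list[TrophallaxisEvent]:
    """Drop exchanges shorter than ``min_duration`` seconds, keeping order.

    The boundary is inclusive: an exchange of exactly ``min_duration``
    seconds is kept, since only interactions *under* the threshold are
    regarded as too brief for nectar transfer.
    """
    return [e for e in events if e.duration >= min_duration]


def code_hygienic_status(roster: Sequence[IndividualRecord],
                         events: Sequence[TrophallaxisEvent]) -> dict[str, bool]:
    """Code each roster individual as hygienic or not.

    An individual is hygienic iff it performed at least one hygienic act
    and it is *not* the case that all of its social interactions (as
    donor or receiver) started strictly before its earliest act.  An
    individual with acts but no recorded interactions is coded hygienic.
    Interactions exactly simultaneous with the earliest act do not count
    as "prior" (strict precedence); such ties are reported via logging.
    """
    event_times: dict[str, list[float]] = {}
    for e in events:
        for ind in e.participants():
            event_times.setdefault(ind, []).append(e.start_time)

    flags: dict[str, bool] = {}
    for rec in roster:
        if not rec.hygienic_acts:
            flags[rec.id] = False
            continue
        first_act = min(a.act_time for a in rec.hygienic_acts)
        times = event_times.get(rec.id)
        if not times:
            flags[rec.id] = True
            continue
        if any(t == first_act for t in times):
            logger.warning(
                "individual %s has an interaction exactly at its first hygienic "
                "act (t=%s); strict precedence keeps it coded hygienic",
                rec.id, first_act,
            )
        flags[rec.id] = not all(t < first_act for t in times)
    return flags
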