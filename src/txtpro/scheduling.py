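"""Per-patient reporting schedules, prompt/reminder timing, on-time rules.

A :class:`Schedule` holds recurring report queries defined in the patient's
local clock (daily pain chances, an evening attendance query, a weekend
multi-item scale window, daily one-way health tips), plus exception dates
such as school breaks.  Expansion over a horizon yields concrete
:class:`ReportEvent` windows in UTC; :func:`due_actions` decides when the
initial prompt and in-window reminders are due, and reminders are suppressed
as soon as a valid response has arrived.

Default protocols give inpatients three daily pain chances between 07:00 and
19:00 local (2-hour windows at 08:00, 12:00 and 17:00) and a weekly scale
window from Friday 18:00 to Sunday 21:00; outpatients additionally report
school attendance around dinnertime.  All of it is configurable per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Iterable, List, Literal, Optional, Sequence, Set, Tuple, Union
from zoneinfo import ZoneInfo

from dateutil import rrule as du_rrule
from pydantic import BaseModel, ConfigDict, field_validator

UTC = timezone.utc

_WEEKDAY_ICS = ["MO", "TU", "WE", "TH", "FR", "SA", "SU"]


class ScheduleError(ValueError):
    """Configuration errors: unknown timezone, malformed recurrence."""


@dataclass(frozen=True, order=True)
class ReportEvent:
    """One concrete scheduled query instance (timestamps in UTC)."""

    window_start: datetime
    window_end: datetime
    event_id: str
    patient_id: str
    template_id: str
    reminder_offsets: Tuple[timedelta, ...] = ()
    one_way: bool = False
    day: date = None  # patient-local calendar day of the query

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        for off in self.reminder_offsets:
            if not timedelta(0) < off < (self.window_end - self.window_start):
                raise ValueError("reminder offsets must lie strictly inside the window")
        if self.day is None:
            object.__setattr__(self, "day", self.window_start.date())


@dataclass(frozen=True)
class PromptAction:
    kind: Literal["initial_prompt", "reminder"]
    event_id: str
    due_at: datetime


class Recurrence(BaseModel):
    """One recurring query: local clock time, window length, reminders."""

    model_config = ConfigDict(frozen=True)

    template_id: str
    freq: Literal["daily", "weekly"]
    at: time
    window_minutes: int
    weekday: Optional[int] = None  # 0=Monday; required for weekly
    reminder_offsets_minutes: Optional[Tuple[int, ...]] = None
    one_way: bool = False

    @field_validator("window_minutes")
    @classmethod
    def _positive_window(cls, v):
        if v <= 0:
            raise ValueError("window_minutes must be positive")
        return v

    def offsets(self) -> Tuple[int, ...]:
        # default policy: one reminder at the window midpoint
        if self.reminder_offsets_minutes is not None:
            return self.reminder_offsets_minutes
        if self.one_way:
            return ()
        return (self.window_minutes // 2,)


class Schedule(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    timezone: str
    recurrences: Tuple[Recurrence, ...]
    exceptions: frozenset[date] = frozenset()

    @field_validator("timezone")
    @classmethod
    def _known_timezone(cls, v):
        try:
            ZoneInfo(v)
        except Exception as exc:  # KeyError or ZoneInfoNotFoundError
            raise ScheduleError(f"unknown timezone {v!r}") from exc
        return v


def expand(schedule: Schedule, horizon: Tuple[datetime, datetime]) -> List[ReportEvent]:
    """Expand recurrences into concrete events whose windows start in *horizon*.

    A pure function of its arguments: events are localized to the patient
    timezone, exception dates are skipped, and the result is chronologically
    ordered.  Windows are a fixed number of minutes of absolute time anchored
    at the configured local clock time, so daylight-saving transitions move
    the UTC instant but never the local clock time.
    """
    start, end = horizon
    if start.tzinfo is None or end.tzinfo is None:
        raise ScheduleError("horizon timestamps must be timezone-aware")
    if start >= end:
        return []
    tz = ZoneInfo(schedule.timezone)
    # widen the local date sweep by a day each side to cover UTC offset shifts
    first_day = (start.astimezone(tz) - timedelta(days=1)).date()
    last_day = (end.astimezone(tz) + timedelta(days=1)).date()
    events: List[ReportEvent] = []
    for rec in schedule.recurrences:
        if rec.freq == "weekly" and rec.weekday is None:
            raise ScheduleError(f"{rec.template_id}: weekly recurrence needs a weekday")
        freq = du_rrule.DAILY if rec.freq == "daily" else du_rrule.WEEKLY
        rule = du_rrule.rrule(
            freq,
            dtstart=datetime.combine(first_day, time(0, 0)),
            until=datetime.combine(last_day, time(0, 0)),
            byweekday=rec.weekday if rec.freq == "weekly" else None,
        )
        for occ in rule:
            day = occ.date()
            if day in schedule.exceptions:
                continue
            ws_local = datetime.combine(day, rec.at, tzinfo=tz)
            ws = ws_local.astimezone(UTC)
            if not (start <= ws < end):
                continue
            we = ws + timedelta(minutes=rec.window_minutes)
            events.append(
                ReportEvent(
                    window_start=ws,
                    window_end=we,
                    event_id=f"{schedule.patient_id}/{rec.template_id}/{ws_local:%Y-%m-%dT%H:%M}",
                    patient_id=schedule.patient_id,
                    template_id=rec.template_id,
                    reminder_offsets=tuple(timedelta(minutes=m) for m in rec.offsets()),
                    one_way=rec.one_way,
                    day=day,
                )
            )
    events.sort()
    return events


def due_actions(events: Sequence[ReportEvent], response_log: Sequence, now: datetime) -> List[PromptAction]:
    """Prompts and reminders due at or before *now*, never outside a window.

    The initial prompt is due at ``window_start``.  A reminder at each
    configured offset is due only if no valid inbound response to that event
    was logged before the offset time.  ``response_log`` entries need
    ``event_id``, ``direction``, ``classification`` and ``at`` attributes
    (see :class:`txtpro.stats.MessageLogEntry`).
    """
    valid_times: dict[str, List[datetime]] = {}
    for entry in response_log:
        if entry.direction == "inbound" and entry.classification == "valid" and entry.event_id:
            valid_times.setdefault(entry.event_id, []).append(entry.at)
    actions: List[PromptAction] = []
    for ev in events:
        if ev.window_start > now:
            continue
        actions.append(PromptAction("initial_prompt", ev.event_id, ev.window_start))
        if ev.one_way:
            continue
        responded = valid_times.get(ev.event_id, [])
        for off in sorted(ev.reminder_offsets):
            due = ev.window_start + off
            if due > now or due > ev.window_end:
                continue
            if any(t < due for t in responded):
                continue
            actions.append(PromptAction("reminder", ev.event_id, due))
    actions.sort(key=lambda a: (a.due_at, a.event_id, a.kind != "initial_prompt"))
    return actions


def classify_on_time(event: ReportEvent, response_time: datetime) -> bool:
    """True iff the response fell inside the closed completion window."""
    return event.window_start <= response_time <= event.window_end


def response_latency(event: ReportEvent, first_valid_time: datetime) -> float:
    """Minutes from the initial prompt (window start) to the first valid reply.

    Defined only for on-time responses; late or early replies raise.
    """
    if not classify_on_time(event, first_valid_time):
        raise ValueError("latency is defined only for responses inside the window")
    return (first_valid_time - event.window_start).total_seconds() / 60.0


# ---------------------------------------------------------------------------
# Default protocols

def inpatient_protocol(patient_id: str, tz: str = "America/New_York") -> Schedule:
    """Three daily 2-hour pain chances (08/12/17 local), weekend scale, daily tip."""
    return Schedule(
        patient_id=patient_id,
        timezone=tz,
        recurrences=(
            Recurrence(template_id="pain", freq="daily", at=time(8, 0), window_minutes=120),
            Recurrence(template_id="pain", freq="daily", at=time(12, 0), window_minutes=120),
            Recurrence(template_id="pain", freq="daily", at=time(17, 0), window_minutes=120),
            Recurrence(
                template_id="promis8",
                freq="weekly",
                weekday=4,  # Friday evening 19:00 -> Sunday 21:00
                at=time(19, 0),
                window_minutes=50 * 60,
                reminder_offsets_minutes=(25 * 60, 49 * 60),
            ),
            Recurrence(template_id="tip", freq="daily", at=time(16, 0), window_minutes=60, one_way=True),
        ),
    )


def outpatient_protocol(patient_id: str, tz: str = "America/New_York",
                        exceptions: Iterable[date] = ()) -> Schedule:
    """Inpatient protocol plus a dinnertime school-attendance query."""
    base = inpatient_protocol(patient_id, tz)
    return Schedule(
        patient_id=patient_id,
        timezone=tz,
        recurrences=base.recurrences
        + (Recurrence(template_id="attendance", freq="daily", at=time(18, 0), window_minutes=120),),
        exceptions=frozenset(exceptions),
    )


# ---------------------------------------------------------------------------
# iCalendar (RFC 5545) subset: one VEVENT per recurrence with RRULE/EXDATE.

def schedule_to_ics(schedule: Schedule, anchor: date = date(2026, 1, 5)) -> str:
    """Serialize a schedule as an iCalendar document.

    Emits one ``VEVENT`` per recurrence: ``DTSTART;TZID=...`` at the first
    occurrence on/after *anchor*, ``DURATION`` for the window, an ``RRULE``
    (``FREQ=DAILY`` or ``FREQ=WEEKLY;BYDAY=..``), ``EXDATE`` for exception
    dates and private ``X-TXTPRO-*`` properties for the template binding.
    """
    lines = [
        "BEGIN:VCALENDAR",
        "VERSION:2.0",
        "PRODID:-//txtpro//schedule//EN",
        f"X-TXTPRO-PATIENT:{schedule.patient_id}",
        f"X-TXTPRO-TZID:{schedule.timezone}",
    ]
    for i, rec in enumerate(schedule.recurrences):
        first = anchor
        if rec.freq == "weekly":
            first = anchor + timedelta(days=(rec.weekday - anchor.weekday()) % 7)
        dtstart = datetime.combine(first, rec.at)
        rrule = "FREQ=DAILY" if rec.freq == "daily" else f"FREQ=WEEKLY;BYDAY={_WEEKDAY_ICS[rec.weekday]}"
        lines += [
            "BEGIN:VEVENT",
            f"UID:{schedule.patient_id}-{rec.template_id}-{i}@txtpro",
            f"DTSTART;TZID={schedule.timezone}:{dtstart:%Y%m%dT%H%M%S}",
            f"DURATION:PT{rec.window_minutes}M",
            f"RRULE:{rrule}",
        ]
        if schedule.exceptions:
            stamps = ",".join(
                f"{datetime.combine(d, rec.at):%Y%m%dT%H%M%S}" for d in sorted(schedule.exceptions)
            )
            lines.append(f"EXDATE;TZID={schedule.timezone}:{stamps}")
        lines += [
            f"SUMMARY:{rec.template_id} report",
            f"X-TXTPRO-TEMPLATE:{rec.template_id}",
            f"X-TXTPRO-REMINDERS:{','.join(str(m) for m in rec.offsets())}",
            f"X-TXTPRO-ONEWAY:{'TRUE' if rec.one_way else 'FALSE'}",
            "END:VEVENT",
        ]
    lines.append("END:VCALENDAR")
    return "\r\n".join(lines) + "\r\n"


def schedule_from_ics(text: str) -> Schedule:
    """Parse a schedule from the iCalendar subset written by :func:`schedule_to_ics`."""
    # unfold continuation lines (RFC 5545 §3.1)
    unfolded: List[str] = []
    for raw in text.replace("\r\n", "\n").split("\n"):
        if raw.startswith((" ", "\t")) and unfolded:
            unfolded[-1] += raw[1:]
        elif raw:
            unfolded.append(raw)

    patient_id, tzname = "", ""
    recurrences: List[Recurrence] = []
    exceptions: Set[date] = set()
    event: dict = {}
    in_event = False
    for line in unfolded:
        name, _, value = line.partition(":")
        prop = name.split(";", 1)[0].upper()
        if prop == "X-TXTPRO-PATIENT":
            patient_id = value
        elif prop == "X-TXTPRO-TZID":
            tzname = value
        elif prop == "BEGIN" and value == "VEVENT":
            in_event, event = True, {}
        elif prop == "END" and value == "VEVENT":
            in_event = False
            recurrences.append(_recurrence_from_event(event))
            for stamp in event.get("EXDATE", "").split(","):
                if stamp:
                    exceptions.add(datetime.strptime(stamp, "%Y%m%dT%H%M%S").date())
        elif in_event:
            event[prop] = value
    if not tzname:
        raise ScheduleError("calendar lacks X-TXTPRO-TZID")
    return Schedule(
        patient_id=patient_id,
        timezone=tzname,
        recurrences=tuple(recurrences),
        exceptions=frozenset(exceptions),
    )


def _recurrence_from_event(event: dict) -> Recurrence:
    try:
        dtstart = datetime.strptime(event["DTSTART"], "%Y%m%dT%H%M%S")
        rrule_parts = dict(
            part.split("=", 1) for part in event["RRULE"].split(";") if "=" in part
        )
        freq = rrule_parts["FREQ"].lower()
        duration = event["DURATION"]
        if not (duration.startswith("PT") and duration.endswith("M")):
            raise ScheduleError(f"unsupported DURATION {duration!r}")
        window_minutes = int(duration[2:-1])
    except (KeyError, ValueError) as exc:
        raise ScheduleError(f"malformed VEVENT: {exc}") from exc
    if freq not in ("daily", "weekly"):
        raise ScheduleError(f"unsupported RRULE FREQ {freq!r}")
    weekday = None
    if freq == "weekly":
        byday = rrule_parts.get("BYDAY")
        weekday = _WEEKDAY_ICS.index(byday) if byday else dtstart.weekday()
    offsets = None
    if "X-TXTPRO-REMINDERS" in event:
        offsets = tuple(int(m) for m in event["X-TXTPRO-REMINDERS"].split(",") if m)
    return Recurrence(
        template_id=event.get("X-TXTPRO-TEMPLATE", event.get("SUMMARY", "report").split()[0]),
        freq=freq,
        at=dtstart.time(),
        window_minutes=window_minutes,
        weekday=weekday,
        reminder_offsets_minutes=offsets,
        one_way=event.get("X-TXTPRO-ONEWAY", "FALSE").upper() == "TRUE",
    )
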