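"""Message log persistence and the trial outcome statistics.

The append-only message log records every inbound and outbound message with
a classification (``valid``, ``invalid``, ``prompt``, ``reminder``,
``instruction``, ``one_way``, ``other``).  The statistics layer condenses a
log and the expanded schedule into the feasibility metrics of a two-way
text-messaging trial:

- *compliance rate*: patient-days with at least one valid report of a
  template over patient-days with at least one scheduled query (late valid
  reports still count toward compliance);
- *validity rate*: valid received messages over all received messages, where
  an invalid attempt followed by a valid retry for the same query collapses
  into one received message that is valid and *corrected*;
- *correction rate*: corrected valid messages over valid messages;
- *on-time rate*: valid messages inside their window, reported both over
  valid messages and over received messages (published trial tables have
  used either denominator);
- *mean latency*: average minutes from the initial prompt to each on-time
  valid message;
- *weekly scale compliance*: query weeks with at least one valid multi-item
  scale answer over all query weeks.

Zero-denominator statistics are reported as ``None`` (absent), never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple, Union

import pandas as pd

from .scheduling import ReportEvent, classify_on_time, response_latency

Classification = Literal[
    "valid", "invalid", "one_way", "reminder", "prompt", "instruction", "other"
]


@dataclass(frozen=True)
class MessageLogEntry:
    patient_id: str
    direction: Literal["inbound", "outbound"]
    at: datetime
    raw_text: str
    classification: Classification
    event_id: Optional[str] = None
    template_id: Optional[str] = None
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.corrected and not (self.direction == "inbound" and self.classification == "valid"):
            raise ValueError("corrected applies only to valid inbound entries")
        if self.direction == "inbound" and self.classification == "valid" and not self.event_id:
            raise ValueError("valid inbound entries must reference an event")


@dataclass(frozen=True)
class ReceivedMessage:
    """One collapsed received-message outcome (see module docstring)."""

    patient_id: str
    event_id: str
    template_id: Optional[str]
    at: datetime
    valid: bool
    corrected: bool = False


@dataclass
class TrialStats:
    """Aggregate counts and rates for one template (or template group)."""

    template_id: str
    query_days: int = 0
    compliant_days: int = 0
    messages_received: int = 0
    messages_valid: int = 0
    messages_corrected: int = 0
    messages_on_time: int = 0
    mean_latency_minutes: Optional[float] = None

    @property
    def compliance_rate(self) -> Optional[float]:
        return self.compliant_days / self.query_days if self.query_days else None

    @property
    def validity_rate(self) -> Optional[float]:
        return self.messages_valid / self.messages_received if self.messages_received else None

    @property
    def correction_rate(self) -> Optional[float]:
        return self.messages_corrected / self.messages_valid if self.messages_valid else None

    @property
    def on_time_rate(self) -> Optional[float]:
        return self.messages_on_time / self.messages_valid if self.messages_valid else None

    @property
    def on_time_rate_over_received(self) -> Optional[float]:
        return self.messages_on_time / self.messages_received if self.messages_received else None

    def check(self) -> None:
        """Assert the chain inequalities every consistent log satisfies."""
        assert self.compliant_days <= self.query_days
        assert self.messages_on_time <= self.messages_valid <= self.messages_received
        assert self.messages_corrected <= self.messages_valid


# ---------------------------------------------------------------------------
# Collapsing inbound traffic into received-message outcomes

def received_messages(
    log: Sequence[MessageLogEntry], template_id: Optional[str] = None
) -> List[ReceivedMessage]:
    """Collapse inbound report traffic into received-message outcomes.

    Walking each event's inbound entries in time order, every valid entry is
    one received message (carrying its ``corrected`` flag); a maximal run of
    invalid attempts not followed by any valid entry for that event counts
    as a single received message that stayed invalid.
    """
    by_event: Dict[Tuple[str, str], List[MessageLogEntry]] = {}
    for e in log:
        if e.direction != "inbound" or e.classification not in ("valid", "invalid"):
            continue
        if template_id is not None and e.template_id != template_id:
            continue
        if not e.event_id:
            continue
        by_event.setdefault((e.patient_id, e.event_id), []).append(e)
    outcomes: List[ReceivedMessage] = []
    for (pid, eid), entries in by_event.items():
        entries.sort(key=lambda e: e.at)
        open_invalid: Optional[MessageLogEntry] = None
        for e in entries:
            if e.classification == "invalid":
                open_invalid = e
            else:
                outcomes.append(
                    ReceivedMessage(pid, eid, e.template_id, e.at, True, e.corrected)
                )
                open_invalid = None
        if open_invalid is not None:
            outcomes.append(
                ReceivedMessage(pid, eid, open_invalid.template_id, open_invalid.at, False)
            )
    outcomes.sort(key=lambda o: (o.at, o.event_id))
    return outcomes


def _event_map(events: Sequence[ReportEvent]) -> Dict[str, ReportEvent]:
    return {ev.event_id: ev for ev in events}


# ---------------------------------------------------------------------------
# Individual statistics

def compliance_rate(
    log: Sequence[MessageLogEntry], events: Sequence[ReportEvent], template_id: str
) -> Optional[float]:
    """Patient-days with >=1 valid report / patient-days with >=1 scheduled query."""
    emap = _event_map(events)
    query_days = {
        (ev.patient_id, ev.day) for ev in events if ev.template_id == template_id and not ev.one_way
    }
    if not query_days:
        return None
    compliant = set()
    for e in log:
        if e.direction == "inbound" and e.classification == "valid" and e.template_id == template_id:
            ev = emap.get(e.event_id)
            if ev is not None and (ev.patient_id, ev.day) in query_days:
                compliant.add((ev.patient_id, ev.day))
    return len(compliant) / len(query_days)


def validity_rate(log: Sequence[MessageLogEntry], template_id: str) -> Optional[float]:
    outcomes = received_messages(log, template_id)
    if not outcomes:
        return None
    return sum(o.valid for o in outcomes) / len(outcomes)


def correction_rate(log: Sequence[MessageLogEntry], template_id: str) -> Optional[float]:
    valid = [o for o in received_messages(log, template_id) if o.valid]
    if not valid:
        return None
    return sum(o.corrected for o in valid) / len(valid)


def on_time_rate(
    log: Sequence[MessageLogEntry],
    events: Sequence[ReportEvent],
    template_id: str,
    denominator: Literal["valid", "received"] = "valid",
) -> Optional[float]:
    """On-time valid messages over valid (default) or over all received."""
    emap = _event_map(events)
    outcomes = received_messages(log, template_id)
    valid = [o for o in outcomes if o.valid]
    denom = len(valid) if denominator == "valid" else len(outcomes)
    if not denom:
        return None
    on_time = sum(
        1 for o in valid if o.event_id in emap and classify_on_time(emap[o.event_id], o.at)
    )
    return on_time / denom


def mean_latency(
    log: Sequence[MessageLogEntry], events: Sequence[ReportEvent], template_id: str
) -> Optional[float]:
    """Average minutes from prompt to message, over on-time valid messages only."""
    emap = _event_map(events)
    latencies = [
        response_latency(emap[o.event_id], o.at)
        for o in received_messages(log, template_id)
        if o.valid and o.event_id in emap and classify_on_time(emap[o.event_id], o.at)
    ]
    if not latencies:
        return None
    return sum(latencies) / len(latencies)


def overall_accuracy(
    log: Sequence[MessageLogEntry], template_ids: Sequence[str]
) -> Optional[float]:
    """Pooled valid / received across templates (and hence settings)."""
    valid = received = 0
    for tid in template_ids:
        outcomes = received_messages(log, tid)
        received += len(outcomes)
        valid += sum(o.valid for o in outcomes)
    if not received:
        return None
    return valid / received


def weekly_scale_compliance(
    log: Sequence[MessageLogEntry], events: Sequence[ReportEvent], template_id: str = "promis8"
) -> Optional[float]:
    """Query weeks with >=1 valid scale answer / total query weeks.

    Each expanded weekly event is one query week.
    """
    weeks = {ev.event_id for ev in events if ev.template_id == template_id and not ev.one_way}
    if not weeks:
        return None
    responded = {
        e.event_id
        for e in log
        if e.direction == "inbound" and e.classification == "valid" and e.event_id in weeks
    }
    return len(responded) / len(weeks)


def summarize(
    log: Sequence[MessageLogEntry], events: Sequence[ReportEvent], template_id: str
) -> TrialStats:
    """Full :class:`TrialStats` for one template over one log + schedule."""
    emap = _event_map(events)
    outcomes = received_messages(log, template_id)
    valid = [o for o in outcomes if o.valid]
    on_time = [o for o in valid if o.event_id in emap and classify_on_time(emap[o.event_id], o.at)]
    query_days = {
        (ev.patient_id, ev.day) for ev in events if ev.template_id == template_id and not ev.one_way
    }
    compliant = {
        (emap[o.event_id].patient_id, emap[o.event_id].day) for o in valid if o.event_id in emap
    } & query_days
    stats = TrialStats(
        template_id=template_id,
        query_days=len(query_days),
        compliant_days=len(compliant),
        messages_received=len(outcomes),
        messages_valid=len(valid),
        messages_corrected=sum(o.corrected for o in valid),
        messages_on_time=len(on_time),
        mean_latency_minutes=mean_latency(log, events, template_id),
    )
    stats.check()
    return stats


def trial_summary(
    log: Sequence[MessageLogEntry],
    events: Sequence[ReportEvent],
    settings: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-(setting, template) summary table.

    *settings* maps patient_id to a setting label (e.g. inpatient /
    outpatient); omitted patients fall under ``"all"``.
    """
    settings = settings or {}
    labels = sorted(set(settings.values())) or ["all"]
    rows = []
    for label in labels:
        pids = {p for p, s in settings.items() if s == label} if settings else None
        sub_log = [e for e in log if pids is None or e.patient_id in pids]
        sub_events = [ev for ev in events if pids is None or ev.patient_id in pids]
        for tid in sorted({ev.template_id for ev in sub_events if not ev.one_way}):
            st = summarize(sub_log, sub_events, tid)
            rows.append(
                {
                    "setting": label,
                    "template_id": tid,
                    "query_days": st.query_days,
                    "compliant_days": st.compliant_days,
                    "messages_received": st.messages_received,
                    "messages_valid": st.messages_valid,
                    "messages_corrected": st.messages_corrected,
                    "messages_on_time": st.messages_on_time,
                    "compliance_pct": _pct(st.compliance_rate),
                    "validity_pct": _pct(st.validity_rate),
                    "correction_pct": _pct(st.correction_rate),
                    "on_time_pct": _pct(st.on_time_rate),
                    "on_time_over_received_pct": _pct(st.on_time_rate_over_received),
                    "mean_latency_min": None
                    if st.mean_latency_minutes is None
                    else round(st.mean_latency_minutes, 1),
                }
            )
    return pd.DataFrame(rows)


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(100.0 * x, 1)


# ---------------------------------------------------------------------------
# Persistence: JSON-lines log, CSV exports

def write_log_jsonl(log: Sequence[MessageLogEntry], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in log:
            record = asdict(e)
            record["at"] = e.at.astimezone(timezone.utc).isoformat()
            fh.write(json.dumps(record) + "\n")


def read_log_jsonl(path: Union[str, Path]) -> List[MessageLogEntry]:
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            record = json.loads(line)
            record["at"] = datetime.fromisoformat(record["at"])
            entries.append(MessageLogEntry(**record))
    return entries


_LOG_COLUMNS = [
    "patient_id", "direction", "at", "raw_text", "classification",
    "event_id", "template_id", "corrected",
]
_REPORT_COLUMNS = ["patient_id", "event_id", "template_id", "at", "text", "parsed"]


def export_message_log_csv(log: Sequence[MessageLogEntry], path: Union[str, Path]) -> None:
    """De-identified RFC 4180 CSV of the full message log."""
    rows = [
        {
            **{c: getattr(e, c) for c in _LOG_COLUMNS if c != "at"},
            "at": e.at.astimezone(timezone.utc).isoformat(),
        }
        for e in log
    ]
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def import_message_log_csv(path: Union[str, Path]) -> List[MessageLogEntry]:
    df = pd.read_csv(path, keep_default_na=False)
    entries = []
    for row in df.to_dict("records"):
        entries.append(
            MessageLogEntry(
                patient_id=str(row["patient_id"]),
                direction=row["direction"],
                at=datetime.fromisoformat(row["at"]),
                raw_text=str(row["raw_text"]),
                classification=row["classification"],
                event_id=row["event_id"] or None,
                template_id=row["template_id"] or None,
                corrected=str(row["corrected"]) == "True",
            )
        )
    return entries


def export_reports_csv(reports: Sequence, path: Union[str, Path]) -> None:
    """One row per stored report: opaque patient id, canonical text, parsed payload.

    *reports* are :class:`txtpro.conversation.StoredReport` records.  Only
    whitelisted columns are written, so no identity field configured
    elsewhere can reach an export.
    """
    rows = [
        {
            "patient_id": r.patient_id,
            "event_id": r.event_id,
            "template_id": r.template_id,
            "at": r.at.astimezone(timezone.utc).isoformat(),
            "text": r.canonical_text,
            "parsed": json.dumps(_payload(r.report)),
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)


def _payload(report) -> dict:
    from .templates import AttendanceReport, PainReport, ScaleReport

    if isinstance(report, PainReport):
        return {"pairs": [list(p) for p in report.pairs], "no_pain": report.no_pain}
    if isinstance(report, AttendanceReport):
        return {"code": report.code}
    if isinstance(report, ScaleReport):
        return {"items": list(report.items)}
    return {}
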