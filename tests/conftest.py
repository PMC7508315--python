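from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from txtpro.scheduling import ReportEvent

UTC = timezone.utc


@pytest.fixture
def make_event():
    """Factory for a simple two-hour query window starting 08:00 UTC."""

    def _make(
        event_id: str = "p1/pain/2026-01-05T08:00",
        patient_id: str = "p1",
        template_id: str = "pain",
        start: datetime = datetime(2026, 1, 5, 8, 0, tzinfo=UTC),
        hours: float = 2.0,
        offsets_minutes=(60,),
        one_way: bool = False,
    ) -> ReportEvent:
        return ReportEvent(
            window_start=start,
            window_end=start + timedelta(hours=hours),
            event_id=event_id,
            patient_id=patient_id,
            template_id=template_id,
            reminder_offsets=tuple(timedelta(minutes=m) for m in offsets_minutes),
            one_way=one_way,
        )

    return _make


@pytest.fixture(scope="session")
def pilot():
    """Events, log and settings of the deterministic trial-count log."""
    from txtpro.simulate import reconstruct_pilot_log

    events, log, settings = reconstruct_pilot_log()
    inpatient = {p for p, s in settings.items() if s == "inpatient"}
    outpatient = {p for p, s in settings.items() if s == "outpatient"}
    return {
        "events": events,
        "log": log,
        "settings": settings,
        "in": ([e for e in log if e.patient_id in inpatient],
               [e for e in events if e.patient_id in inpatient]),
        "out": ([e for e in log if e.patient_id in outpatient],
                [e for e in events if e.patient_id in outpatient]),
    }
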