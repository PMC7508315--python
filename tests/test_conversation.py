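"""Two-way conversation loop: error-proofing, alarms, resubmission, tips."""

from __future__ import annotations

import random
from datetime import datetime, timedelta, timezone

import pytest

from txtpro.conversation import (
    AlarmEvent,
    ConversationState,
    Engine,
    OutboundMessage,
    StoredReport,
    ThresholdPolicy,
    alarm_score,
    handle_inbound,
    handle_resubmission,
    send_health_tip,
)
from txtpro.pools import MessagePool
from txtpro.scheduling import PromptAction
from txtpro.templates import PainReport, parse, builtin_templates

UTC = timezone.utc


def _engine(events, threshold=None):
    policies = {}
    if threshold is not None:
        policies[events[0].patient_id] = ThresholdPolicy(
            patient_id=events[0].patient_id, threshold=threshold, provider_ids=("dr1",)
        )
    return Engine(events=events, policies=policies, ack_text=None)


def _prompt(engine, ev):
    engine.deliver(PromptAction("initial_prompt", ev.event_id, ev.window_start))


# ---------------------------------------------------------------------------
# Threshold alarms

def test_score_above_threshold_alarms(make_event):
    ev = make_event()
    engine = _engine([ev], threshold=5)
    _prompt(engine, ev)
    actions = engine.receive("p1", "P6BACK", ev.window_start + timedelta(minutes=10))
    alarms = [a for a in actions if isinstance(a, AlarmEvent)]
    assert len(alarms) == 1
    assert alarms[0].observed_score == 6 and alarms[0].threshold == 5
    assert alarms[0].provider_ids == ("dr1",)
    assert any(isinstance(a, StoredReport) for a in actions)


def test_score_at_threshold_does_not_alarm(make_event):
    ev = make_event()
    engine = _engine([ev], threshold=5)
    _prompt(engine, ev)
    actions = engine.receive("p1", "P5BACK", ev.window_start + timedelta(minutes=10))
    assert not any(isinstance(a, AlarmEvent) for a in actions)
    assert engine.alarms == []


@pytest.mark.parametrize(
    "pairs,no_pain,score",
    [(((2, "CHEST"), (3, "BELLY")), False, 3), ((), True, 0), (((10, "HEAD"),), False, 10)],
)
def test_alarm_score_is_maximum_intensity(pairs, no_pain, score):
    assert alarm_score(PainReport(pairs=pairs, no_pain=no_pain)) == score


def test_alarm_exists_iff_some_stored_report_crosses_threshold(make_event):
    threshold = 4
    events = [
        make_event(event_id=f"p1/pain/e{i}", start=datetime(2026, 1, 5 + i, 8, tzinfo=UTC))
        for i in range(4)
    ]
    engine = _engine(events, threshold=threshold)
    for ev, text in zip(events, ["P3BACK", "P5UL", "PN", "P4HEAD&9LR"]):
        _prompt(engine, ev)
        engine.receive("p1", text, ev.window_start + timedelta(minutes=5))
    expected = sum(alarm_score(r.report) > threshold for r in engine.reports)
    assert len(engine.alarms) == expected == 2


# ---------------------------------------------------------------------------
# Error-proofing and correction

def test_invalid_then_valid_is_stored_corrected(make_event):
    ev = make_event()
    engine = _engine([ev])
    _prompt(engine, ev)
    first = engine.receive("p1", "2CHEST", ev.window_start + timedelta(minutes=5))
    assert len(first) == 1 and first[0].kind == "instruction"
    assert "P2CHEST&3BELLY" in first[0].text
    state = engine.state_of("p1")
    assert state.attempt_count == 1 and state.had_invalid_attempt
    second = engine.receive("p1", "P2CHEST", ev.window_start + timedelta(minutes=8))
    stored = [a for a in second if isinstance(a, StoredReport)]
    assert len(stored) == 1 and stored[0].corrected
    assert engine.state_of("p1").pending_event is None
    assert engine.state_of("p1").attempt_count == 0


def test_valid_first_try_is_not_corrected(make_event):
    ev = make_event()
    engine = _engine([ev])
    _prompt(engine, ev)
    (stored,) = [
        a for a in engine.receive("p1", "PN", ev.window_start + timedelta(minutes=1))
        if isinstance(a, StoredReport)
    ]
    assert not stored.corrected and stored.canonical_text == "PN"


def test_unlimited_retries_each_resend_instruction(make_event):
    ev = make_event()
    engine = _engine([ev])
    _prompt(engine, ev)
    for i in range(4):
        actions = engine.receive("p1", "garbage", ev.window_start + timedelta(minutes=i + 1))
        assert actions[0].kind == "instruction"
    assert engine.state_of("p1").attempt_count == 4


def test_unprompted_unparseable_message_gets_help_not_storage(make_event):
    ev = make_event()
    engine = _engine([ev])
    actions = engine.receive("p1", "hello??", ev.window_start - timedelta(hours=1))
    assert [a.kind for a in actions] == ["help"]
    assert engine.reports == []
    assert engine.log[0].classification == "other"


def test_late_valid_report_is_recorded_against_past_event(make_event):
    ev = make_event()
    engine = _engine([ev])
    _prompt(engine, ev)
    at = ev.window_end + timedelta(hours=2)
    actions = engine.receive("p1", "P7LL", at)
    stored = [a for a in actions if isinstance(a, StoredReport)]
    assert len(stored) == 1 and stored[0].event_id == ev.event_id


def test_every_inbound_yields_exactly_one_log_entry_and_log_is_append_only(make_event):
    ev = make_event()
    engine = _engine([ev])
    _prompt(engine, ev)
    snapshots = []
    for i, text in enumerate(["junk", "P2BACK", "PN"]):
        before = list(engine.log)
        engine.receive("p1", text, ev.window_start + timedelta(minutes=i + 1))
        inbound = [e for e in engine.log if e.direction == "inbound"]
        assert engine.log[: len(before)] == before  # append-only
        snapshots.append(len(inbound))
    assert snapshots == [1, 2, 3]


def test_stored_reports_always_satisfy_their_template(make_event):
    ev = make_event()
    engine = _engine([ev])
    _prompt(engine, ev)
    templates = builtin_templates()
    for i, text in enumerate(["P0HEAD", "P2NOSE", "p3ul&4lr", "PN"]):
        engine.receive("p1", text, ev.window_start + timedelta(minutes=i + 1))
    assert engine.reports  # validation is the only gate to storage
    for r in engine.reports:
        assert parse(r.canonical_text, templates[r.template_id]).report == r.report


# ---------------------------------------------------------------------------
# Scale resubmission (last write wins within the window)

def test_scale_resubmission_within_window_supersedes(make_event):
    ev = make_event(template_id="promis8", event_id="p1/promis8/e0")
    engine = _engine([ev])
    _prompt(engine, ev)
    engine.receive("p1", "01324101", ev.window_start + timedelta(minutes=10))
    engine.receive("p1", "01324102", ev.window_start + timedelta(minutes=50))
    assert len(engine.reports) == 1
    assert engine.reports[0].report.items[-1] == 2
    # both raw messages remain in the log
    valids = [e for e in engine.log if e.classification == "valid"]
    assert [e.raw_text for e in valids] == ["01324101", "01324102"]


def test_scale_resubmission_after_window_close_is_logged_not_applied(make_event):
    ev = make_event(template_id="promis8", event_id="p1/promis8/e0")
    engine = _engine([ev])
    _prompt(engine, ev)
    engine.receive("p1", "01324101", ev.window_start + timedelta(minutes=10))
    engine.receive("p1", "44444444", ev.window_end + timedelta(hours=1))
    assert engine.reports[0].report.items == (0, 1, 3, 2, 4, 1, 0, 1)
    assert sum(e.classification == "valid" for e in engine.log) == 2


def test_invalid_resubmission_leaves_report_unchanged(make_event):
    ev = make_event(template_id="promis8", event_id="p1/promis8/e0")
    prior = StoredReport(
        patient_id="p1", event_id=ev.event_id, template_id="promis8",
        at=ev.window_start + timedelta(minutes=5),
        report=parse("01324101", builtin_templates()["promis8"]).report,
        canonical_text="01324101",
    )
    state = ConversationState(patient_id="p1")
    actions, current = handle_resubmission(
        state, prior, "0132410", ev.window_start + timedelta(minutes=30), event=ev
    )
    assert current is prior
    assert actions[0].kind == "instruction" and "01324101" in actions[0].text


# ---------------------------------------------------------------------------
# One-way health tips

def test_tip_is_one_way_and_keeps_query_pending(make_event):
    pool = MessagePool(pool_id="tips", subsets={"a": [f"tip {i}" for i in range(10)]})
    ev = make_event()
    tip_ev = make_event(event_id="p1/tip/e0", template_id="tip", one_way=True)
    engine = Engine(events=[ev, tip_ev], tip_pool=pool, rng=random.Random(1), ack_text=None)
    _prompt(engine, ev)
    assert engine.state_of("p1").pending_event == ev.event_id
    engine.deliver(PromptAction("initial_prompt", tip_ev.event_id, tip_ev.window_start))
    assert engine.state_of("p1").pending_event == ev.event_id  # still pending
    one_way = [e for e in engine.log if e.classification == "one_way"]
    assert len(one_way) == 1 and one_way[0].raw_text.startswith("tip")


def test_consecutive_tips_differ_when_pool_allows():
    pool = MessagePool(pool_id="tips", subsets={"a": ["alpha", "beta", "gamma"]})
    state = ConversationState(patient_id="p1")
    rng = random.Random(3)
    at = datetime(2026, 1, 5, 16, tzinfo=UTC)
    first, state = send_health_tip(pool, state, rng, at)
    second, state = send_health_tip(pool, state, rng, at + timedelta(days=1))
    assert isinstance(first, OutboundMessage) and first.kind == "tip"
    assert first.text != second.text
    assert state.pending_event is None


# ---------------------------------------------------------------------------
# Functional wrapper

def test_handle_inbound_functional_surface(make_event):
    ev = make_event()
    state = ConversationState(
        patient_id="p1", pending_event=ev.event_id, pending_template="pain"
    )
    policy = ThresholdPolicy(patient_id="p1", threshold=5)
    actions, new_state = handle_inbound(
        state, "P6BACK", ev.window_start + timedelta(minutes=3), event=ev, policy=policy
    )
    assert any(isinstance(a, AlarmEvent) for a in actions)
    assert new_state.pending_event is None
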