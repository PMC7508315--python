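"""The two-way conversation state machine.

Prompts go out when the scheduler says so; every inbound message is parsed
against the pending query's template.  An invalid message triggers an
error-proofing instruction (embedding a valid example) and leaves the query
pending; a valid message is stored — flagged *corrected* when an invalid
attempt preceded it — may trigger a threshold alarm, and clears the query.
Multi-item scale answers may be resent within their window (last write
wins); pain and attendance duplicates within a window are stored as
additional reports, since multiple daily pain reports are encouraged.

Threshold alarms are strict: a patient whose pain threshold is 5 alarms on a
report scoring 6, not 5.  The score of a multi-site pain report is its
maximum intensity (0 for a no-pain report) — the clinically conservative
aggregation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .pools import MessagePool, select
from .scheduling import PromptAction, ReportEvent
from .stats import MessageLogEntry
from .templates import (
    PainReport,
    ParsedReport,
    ScaleReport,
    TemplateSpec,
    ValidationResult,
    builtin_templates,
    parse,
    render,
)

HELP_TEXT = (
    "We did not understand your message and no report is currently due. "
    "If you meant to send a report, please wait for the next prompt or "
    "resend it in the format shown in our last question."
)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Personalized alert rule: alarm when a score exceeds the threshold."""

    patient_id: str
    threshold: int
    metric: str = "pain"
    provider_ids: Tuple[str, ...] = ()


@dataclass(frozen=True)
class AlarmEvent:
    patient_id: str
    provider_ids: Tuple[str, ...]
    triggering_report: ParsedReport
    observed_score: int
    threshold: int
    at: datetime

    def __post_init__(self) -> None:
        if self.observed_score <= self.threshold:
            raise ValueError("alarms require observed_score > threshold")


@dataclass(frozen=True)
class StoredReport:
    patient_id: str
    event_id: str
    template_id: str
    at: datetime
    report: ParsedReport
    canonical_text: str
    corrected: bool = False


@dataclass(frozen=True)
class OutboundMessage:
    """An outbound action: prompt, reminder, instruction, ack, tip or help."""

    kind: str
    text: str


Action = Union[OutboundMessage, StoredReport, AlarmEvent]


@dataclass(frozen=True)
class ConversationState:
    patient_id: str
    pending_event: Optional[str] = None
    pending_template: Optional[str] = None
    attempt_count: int = 0
    had_invalid_attempt: bool = False
    last_outbound: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.pending_event is None and self.attempt_count != 0:
            raise ValueError("attempt_count must be 0 without a pending event")
        if self.had_invalid_attempt and self.attempt_count < 1:
            raise ValueError("had_invalid_attempt implies attempt_count >= 1")


def alarm_score(report: PainReport) -> int:
    """Alert score of a pain report: maximum intensity, 0 for no pain."""
    if report.no_pain:
        return 0
    return max(intensity for intensity, _ in report.pairs)


def check_alarm(
    report: ParsedReport, policy: Optional[ThresholdPolicy], at: datetime
) -> Optional[AlarmEvent]:
    """Alarm iff a pain report scores strictly above the patient threshold."""
    if policy is None or not isinstance(report, PainReport):
        return None
    score = alarm_score(report)
    if score > policy.threshold:
        return AlarmEvent(
            patient_id=policy.patient_id,
            provider_ids=policy.provider_ids,
            triggering_report=report,
            observed_score=score,
            threshold=policy.threshold,
            at=at,
        )
    return None


def send_health_tip(
    pool: MessagePool, state: ConversationState, rng: random.Random, at: datetime
) -> Tuple[OutboundMessage, ConversationState]:
    """One-way tip: emits a pool message, never touches the pending query."""
    text = select(pool, state.patient_id, rng)
    return OutboundMessage("tip", text), replace(state, last_outbound=at)


class Engine:
    """Ties templates, schedule, pools and policies into a message loop.

    The transport contract is minimal: :meth:`deliver` pushes scheduler
    actions out, :meth:`receive` consumes ``(patient_id, text, timestamp)``
    triples from any gateway or simulator.  Everything is appended to
    ``self.log`` (append-only); valid reports land in ``self.reports`` and
    threshold crossings in ``self.alarms``.
    """

    def __init__(
        self,
        events: Sequence[ReportEvent],
        templates: Optional[Dict[str, TemplateSpec]] = None,
        policies: Optional[Dict[str, ThresholdPolicy]] = None,
        tip_pool: Optional[MessagePool] = None,
        rng: Optional[random.Random] = None,
        prompt_texts: Optional[Dict[str, str]] = None,
        ack_text: Optional[str] = "Thank you, your report was recorded.",
    ) -> None:
        self.templates = templates or builtin_templates()
        self.events = {ev.event_id: ev for ev in events}
        self.policies = policies or {}
        self.tip_pool = tip_pool
        self.rng = rng or random.Random(0)
        self.prompt_texts = prompt_texts or {}
        self.ack_text = ack_text
        self.log: List[MessageLogEntry] = []
        self.reports: List[StoredReport] = []
        self.alarms: List[AlarmEvent] = []
        self.states: Dict[str, ConversationState] = {}

    # -- outbound ----------------------------------------------------------

    def state_of(self, patient_id: str) -> ConversationState:
        return self.states.setdefault(patient_id, ConversationState(patient_id=patient_id))

    def deliver(self, action: PromptAction) -> None:
        """Send a scheduled prompt or reminder (or a one-way tip)."""
        ev = self.events[action.event_id]
        state = self.state_of(ev.patient_id)
        if ev.one_way:
            if self.tip_pool is None:
                return
            msg, new_state = send_health_tip(self.tip_pool, state, self.rng, action.due_at)
            self.states[ev.patient_id] = new_state
            self._log_outbound(ev.patient_id, msg.text, action.due_at, "one_way", ev.event_id, ev.template_id)
            return
        spec = self.templates[ev.template_id]
        text = self.prompt_texts.get(
            ev.template_id,
            f"Please send your {ev.template_id} report. For example: '{spec.valid_example}'.",
        )
        kind = "prompt" if action.kind == "initial_prompt" else "reminder"
        if action.kind == "initial_prompt":
            self.states[ev.patient_id] = replace(
                state,
                pending_event=ev.event_id,
                pending_template=ev.template_id,
                attempt_count=0,
                had_invalid_attempt=False,
                last_outbound=action.due_at,
            )
        else:
            self.states[ev.patient_id] = replace(state, last_outbound=action.due_at)
        self._log_outbound(ev.patient_id, text, action.due_at, kind, ev.event_id, ev.template_id)

    # -- inbound -----------------------------------------------------------

    def receive(self, patient_id: str, text: str, at: datetime) -> List[Action]:
        """Process one inbound message; returns the actions it produced."""
        state = self.state_of(patient_id)
        event, result = self._match(state, patient_id, text, at)

        if event is None and (result is None or not result.valid):
            # nothing pending and nothing parseable: generic help
            self._log_inbound(patient_id, text, at, "other", None, None)
            self._log_outbound(patient_id, HELP_TEXT, at, "instruction", None, None)
            return [OutboundMessage("help", HELP_TEXT)]

        if not result.valid:
            # invalid attempt against the pending query: error-proof and retry
            self._log_inbound(patient_id, text, at, "invalid", event.event_id, event.template_id)
            self.states[patient_id] = replace(
                state, attempt_count=state.attempt_count + 1, had_invalid_attempt=True,
                last_outbound=at,
            )
            self._log_outbound(
                patient_id, result.instruction, at, "instruction", event.event_id, event.template_id
            )
            return [OutboundMessage("instruction", result.instruction)]

        return self._accept(state, event, result, text, at)

    def _accept(
        self,
        state: ConversationState,
        event: ReportEvent,
        result: ValidationResult,
        raw_text: str,
        at: datetime,
    ) -> List[Action]:
        spec = self.templates[event.template_id]
        corrected = state.had_invalid_attempt and state.pending_event == event.event_id
        stored = StoredReport(
            patient_id=event.patient_id,
            event_id=event.event_id,
            template_id=event.template_id,
            at=at,
            report=result.report,
            canonical_text=render(result.report, spec),
            corrected=corrected,
        )
        actions: List[Action] = []
        applied = True
        if isinstance(result.report, ScaleReport):
            applied = self._apply_resubmission(stored, event, at)
        if applied:
            if not isinstance(result.report, ScaleReport):
                self.reports.append(stored)
            actions.append(stored)
        self._log_inbound(
            event.patient_id, raw_text, at, "valid", event.event_id, event.template_id,
            corrected=corrected,
        )
        alarm = check_alarm(result.report, self.policies.get(event.patient_id), at)
        if alarm is not None:
            self.alarms.append(alarm)
            actions.append(alarm)
        if state.pending_event == event.event_id:
            self.states[event.patient_id] = replace(
                state, pending_event=None, pending_template=None,
                attempt_count=0, had_invalid_attempt=False,
            )
        if self.ack_text:
            self._log_outbound(
                event.patient_id, self.ack_text, at, "other", event.event_id, event.template_id
            )
            actions.append(OutboundMessage("ack", self.ack_text))
        return actions

    def _apply_resubmission(self, stored: StoredReport, event: ReportEvent, at: datetime) -> bool:
        """Last-write-wins for scale reports while the window is open.

        Returns False when a prior report exists and the window has closed:
        the message stays in the log but the stored answer is unchanged.
        """
        prior_idx = [
            i for i, r in enumerate(self.reports) if r.event_id == event.event_id
        ]
        if not prior_idx:
            self.reports.append(stored)
            return True
        if at > event.window_end:
            return False
        self.reports[prior_idx[-1]] = stored
        return True

    def _match(
        self, state: ConversationState, patient_id: str, text: str, at: datetime
    ) -> Tuple[Optional[ReportEvent], Optional[ValidationResult]]:
        """Attribute an inbound message to an event and parse it.

        The pending query's template is tried first; if the message instead
        parses under another template, it is attributed to the most recent
        event of that template whose window has opened (late replies are
        still attributed, recorded and counted toward compliance).
        """
        pending = self.events.get(state.pending_event) if state.pending_event else None
        if pending is not None:
            result = parse(text, self.templates[pending.template_id])
            if result.valid:
                return pending, result
        candidates = sorted(
            (ev for ev in self.events.values()
             if ev.patient_id == patient_id and not ev.one_way and ev.window_start <= at),
            key=lambda ev: ev.window_start,
            reverse=True,
        )
        tried = {pending.template_id} if pending is not None else set()
        for ev in candidates:
            if ev.template_id in tried:
                continue
            tried.add(ev.template_id)
            result = parse(text, self.templates[ev.template_id])
            if result.valid:
                return ev, result
        if pending is not None:
            # invalid under everything: report the error against the pending query
            return pending, parse(text, self.templates[pending.template_id])
        return None, None

    # -- logging -----------------------------------------------------------

    def _log_inbound(self, pid, text, at, classification, event_id, template_id, corrected=False):
        self.log.append(
            MessageLogEntry(
                patient_id=pid, direction="inbound", at=at, raw_text=text,
                classification=classification, event_id=event_id,
                template_id=template_id, corrected=corrected,
            )
        )

    def _log_outbound(self, pid, text, at, classification, event_id, template_id):
        self.log.append(
            MessageLogEntry(
                patient_id=pid, direction="outbound", at=at, raw_text=text,
                classification=classification, event_id=event_id, template_id=template_id,
            )
        )


def handle_resubmission(
    state: ConversationState,
    prior_report: StoredReport,
    text: str,
    at: datetime,
    *,
    event: ReportEvent,
    templates: Optional[Dict[str, TemplateSpec]] = None,
) -> Tuple[List[Action], Optional[StoredReport]]:
    """Re-send of a multi-item scale answer: last write wins within the window.

    Returns the actions plus the report now on record for the event.  An
    invalid resubmission triggers the error-proofing instruction; a
    resubmission after the window closed is acknowledged as logged-only and
    the stored report stays unchanged.
    """
    templates = templates or builtin_templates()
    spec = templates[prior_report.template_id]
    result = parse(text, spec)
    if not result.valid:
        return [OutboundMessage("instruction", result.instruction)], prior_report
    if at > event.window_end:
        return [], prior_report
    superseding = StoredReport(
        patient_id=prior_report.patient_id,
        event_id=prior_report.event_id,
        template_id=prior_report.template_id,
        at=at,
        report=result.report,
        canonical_text=render(result.report, spec),
    )
    return [superseding], superseding


# ---------------------------------------------------------------------------
# Functional surface mirroring the engine for single-exchange use

def handle_inbound(
    state: ConversationState,
    text: str,
    at: datetime,
    *,
    event: Optional[ReportEvent],
    templates: Optional[Dict[str, TemplateSpec]] = None,
    policy: Optional[ThresholdPolicy] = None,
) -> Tuple[List[Action], ConversationState]:
    """Process one inbound message against one pending event, statelessly.

    Thin functional wrapper over :class:`Engine` for callers that manage
    their own log; the engine is the full conversational loop.
    """
    engine = Engine(
        events=[event] if event is not None else [],
        templates=templates,
        policies={state.patient_id: policy} if policy else {},
    )
    engine.states[state.patient_id] = state
    actions = engine.receive(state.patient_id, text, at)
    return actions, engine.state_of(state.patient_id)
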