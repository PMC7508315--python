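"""Synthetic cohort simulator: the stand-in for a live SMS gateway.

Generates adolescent patient profiles with configurable per-query response
probability, per-response format-error probability and a latency
distribution; expands each patient's protocol schedule; and drives the
conversation engine with the resulting inbound traffic.  A ground-truth
record of every generated message's intended classification is emitted
alongside, so downstream tests never re-derive labels from the system under
test.

Defaults emulate the observed behaviour of an engaged adolescent cohort:
95% response probability per query, 2% format-error probability with an 80%
chance of retrying after the error-proofing instruction, and a log-normal
response latency with a 30-minute median.  Enrollment defaults are 5 days
for inpatients and 20 for outpatients.  The pain process (daily Bernoulli
pain occurrence, geometric site count capped at the eight-location
vocabulary, uniform intensities) is a plain fixture with no claim of
clinical realism.

:func:`reconstruct_pilot_log` instead builds a *deterministic* log whose
marginal counts equal a published pilot trial's tallies, so the statistics
layer can be verified against printed percentages without raw data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .conversation import Engine, StoredReport, ThresholdPolicy
from .pools import MessagePool, shipped_tip_pool
from .scheduling import (
    PromptAction,
    ReportEvent,
    Schedule,
    due_actions,
    expand,
    inpatient_protocol,
    outpatient_protocol,
)
from .stats import MessageLogEntry
from .templates import (
    AttendanceReport,
    PainReport,
    ScaleReport,
    TemplateSpec,
    builtin_templates,
    parse,
    render,
)

UTC = timezone.utc


class LatencySpec(BaseModel):
    """Non-negative response-latency distribution, in minutes."""

    model_config = ConfigDict(frozen=True)

    family: Literal["lognormal", "exponential", "fixed"] = "lognormal"
    median_minutes: float = 30.0
    sigma: float = 0.6
    mean_minutes: float = 30.0
    value_minutes: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "lognormal":
            return float(rng.lognormal(mean=np.log(self.median_minutes), sigma=self.sigma))
        if self.family == "exponential":
            return float(rng.exponential(self.mean_minutes))
        return self.value_minutes


class PainProcess(BaseModel):
    """Daily pain fixture: Bernoulli occurrence, geometric site count."""

    model_config = ConfigDict(frozen=True)

    p_pain_day: float = 0.6
    site_continue_p: float = 0.35  # chance of each additional site
    max_sites: int = 8


class PatientProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    setting: Literal["inpatient", "outpatient"]
    respond_probability: float = 0.95
    format_error_probability: float = 0.02
    retry_probability: float = 0.8
    latency: LatencySpec = LatencySpec()
    pain_process: PainProcess = PainProcess()
    attendance_probs: Dict[str, float] = Field(
        default_factory=lambda: {"WD": 0.80, "AM": 0.07, "AF": 0.07, "AW": 0.06}
    )
    scale_item_probs: Tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    enrollment_length_days: int = 0  # 0 -> setting default (5 in / 20 out)
    pain_threshold: Optional[int] = None
    templates: Optional[Tuple[str, ...]] = None  # restrict the protocol, e.g. ("pain",)

    @field_validator("respond_probability", "format_error_probability", "retry_probability")
    @classmethod
    def _probability(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("attendance_probs")
    @classmethod
    def _attendance_sums_to_one(cls, v):
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("attendance probabilities must sum to 1")
        return v

    def enrollment_days(self) -> int:
        if self.enrollment_length_days > 0:
            return self.enrollment_length_days
        return 5 if self.setting == "inpatient" else 20


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    cohort: Tuple[PatientProfile, ...]
    seed: int = 0
    start: date = date(2026, 1, 5)
    timezone: str = "America/New_York"


@dataclass(frozen=True)
class GroundTruth:
    """Intended classification of one generated inbound message."""

    patient_id: str
    event_id: str
    template_id: str
    at: datetime
    intended: Literal["valid", "invalid"]


@dataclass
class SimulationResult:
    config: SimulationConfig
    events: List[ReportEvent]
    log: List[MessageLogEntry]
    reports: List[StoredReport]
    alarms: list
    ground_truth: List[GroundTruth]

    @property
    def settings(self) -> Dict[str, str]:
        return {p.patient_id: p.setting for p in self.config.cohort}


def default_config(seed: int = 0, n_inpatient: int = 4, n_outpatient: int = 4) -> SimulationConfig:
    cohort = [
        PatientProfile(patient_id=f"in{i:02d}", setting="inpatient")
        for i in range(1, n_inpatient + 1)
    ] + [
        PatientProfile(patient_id=f"out{i:02d}", setting="outpatient")
        for i in range(1, n_outpatient + 1)
    ]
    return SimulationConfig(cohort=tuple(cohort), seed=seed)


# ---------------------------------------------------------------------------
# Message generation

def _draw_valid_text(profile: PatientProfile, spec: TemplateSpec, rng: np.random.Generator) -> str:
    if spec.kind == "pair_list":
        pp = profile.pain_process
        if rng.random() >= pp.p_pain_day:
            return render(PainReport(pairs=(), no_pain=True), spec)
        n_sites = 1
        while n_sites < min(pp.max_sites, len(spec.location_vocabulary)) and rng.random() < pp.site_continue_p:
            n_sites += 1
        locations = rng.choice(len(spec.location_vocabulary), size=n_sites, replace=False)
        lo, hi = spec.intensity_range
        pairs = tuple(
            (int(rng.integers(lo, hi + 1)), spec.location_vocabulary[i]) for i in sorted(locations)
        )
        return render(PainReport(pairs=pairs), spec)
    if spec.kind == "code_choice":
        codes = list(profile.attendance_probs)
        probs = [profile.attendance_probs[c] for c in codes]
        return render(AttendanceReport(code=codes[rng.choice(len(codes), p=probs)]), spec)
    lo, _ = spec.item_range
    probs = np.asarray(profile.scale_item_probs, dtype=float)
    probs = probs / probs.sum()
    items = tuple(int(lo + rng.choice(len(probs), p=probs)) for _ in range(spec.item_count))
    return render(ScaleReport(items=items), spec)


def mutate_to_invalid(valid_text: str, spec: TemplateSpec, rng: np.random.Generator) -> str:
    """Turn a valid message into one that provably fails parsing.

    Mutations: drop the header, push a digit out of range, substitute an
    unknown code, or change the length.  The result is re-parsed; mutation
    kinds are retried until one fails, which is guaranteed to terminate
    because the unknown-code and length mutations always break the grammar.
    """
    candidates: List[str] = []
    if spec.kind == "pair_list":
        if spec.header and valid_text.startswith(spec.header):
            candidates.append(valid_text[len(spec.header):])  # drop header
        candidates.append(spec.header + "0" + "".join(spec.location_vocabulary[:1]))
        candidates.append(spec.header + "2XYZ")  # unknown code
        candidates.append(valid_text + "&")  # dangling separator
    elif spec.kind == "code_choice":
        candidates.append(valid_text + "X")  # not in vocabulary
        candidates.append("QQ")
    else:
        candidates.append(valid_text[:-1])  # wrong length
        hi = spec.item_range[1]
        candidates.append(str(hi + 1) + valid_text[1:])  # out-of-range digit
    order = list(rng.permutation(len(candidates)))
    for i in order:
        if not parse(candidates[i], spec).valid:
            return candidates[i]
    raise AssertionError("unreachable: some mutation always fails parsing")


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full loop: schedules -> prompts/reminders -> traffic -> log.

    Reproducible: the same config (including seed) yields a byte-identical
    log.  For every two-way event the patient responds with
    ``respond_probability`` at ``window_start + latency``; with
    ``format_error_probability`` the first message is an invalid mutation,
    followed (with ``retry_probability``) by the corrected valid message a
    few minutes later.
    """
    rng = np.random.default_rng(config.seed)
    templates = builtin_templates()
    all_events: List[ReportEvent] = []
    policies: Dict[str, ThresholdPolicy] = {}
    timeline: List[Tuple[datetime, int, str, object]] = []  # (time, priority, patient, payload)

    for profile in config.cohort:
        days = profile.enrollment_days()
        schedule = (
            inpatient_protocol(profile.patient_id, config.timezone)
            if profile.setting == "inpatient"
            else outpatient_protocol(profile.patient_id, config.timezone)
        )
        if profile.templates is not None:
            schedule = Schedule(
                patient_id=schedule.patient_id,
                timezone=schedule.timezone,
                recurrences=tuple(
                    r for r in schedule.recurrences if r.template_id in profile.templates
                ),
                exceptions=schedule.exceptions,
            )
        tz_start = datetime.combine(config.start, time(0, 0), tzinfo=UTC)
        horizon = (tz_start, tz_start + timedelta(days=days))
        events = expand(schedule, horizon)
        all_events.extend(events)
        if profile.pain_threshold is not None:
            policies[profile.patient_id] = ThresholdPolicy(
                patient_id=profile.patient_id, threshold=profile.pain_threshold
            )
        for ev in events:
            timeline.append(
                (ev.window_start, 0, ev.patient_id, PromptAction("initial_prompt", ev.event_id, ev.window_start))
            )
            if ev.one_way:
                continue
            spec = templates[ev.template_id]
            responds = rng.random() < profile.respond_probability
            response_time = None
            if responds:
                latency = timedelta(minutes=profile.latency.sample(rng))
                response_time = ev.window_start + latency
                valid_text = _draw_valid_text(profile, spec, rng)
                if rng.random() < profile.format_error_probability:
                    invalid_text = mutate_to_invalid(valid_text, spec, rng)
                    timeline.append((response_time, 1, ev.patient_id, ("inbound", ev, invalid_text, "invalid")))
                    if rng.random() < profile.retry_probability:
                        retry_at = response_time + timedelta(minutes=float(rng.uniform(1, 10)))
                        timeline.append((retry_at, 1, ev.patient_id, ("inbound", ev, valid_text, "valid")))
                else:
                    timeline.append((response_time, 1, ev.patient_id, ("inbound", ev, valid_text, "valid")))
            # reminders fire only when no response has landed before the offset
            for off in ev.reminder_offsets:
                due = ev.window_start + off
                if response_time is None or response_time >= due:
                    timeline.append((due, 0, ev.patient_id, PromptAction("reminder", ev.event_id, due)))

    all_events.sort()
    engine = Engine(
        events=all_events,
        templates=templates,
        policies=policies,
        tip_pool=shipped_tip_pool(),
        rng=random.Random(int(rng.integers(0, 2**31 - 1))),
    )
    ground_truth: List[GroundTruth] = []
    timeline.sort(key=lambda item: (item[0], item[1], item[2], str(item[3])))
    for at, _, _, payload in timeline:
        if isinstance(payload, PromptAction):
            engine.deliver(payload)
        else:
            _, ev, text, intended = payload
            engine.receive(ev.patient_id, text, at)
            ground_truth.append(GroundTruth(ev.patient_id, ev.event_id, ev.template_id, at, intended))
    return SimulationResult(
        config=config,
        events=all_events,
        log=engine.log,
        reports=engine.reports,
        alarms=engine.alarms,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Deterministic reconstruction of a published pilot's marginal counts

PILOT_COUNTS = {
    # setting -> template -> tallies fully determining the printed ratios
    "inpatient": {
        "pain": dict(query_days=118, compliant_days=112, received=383, valid=378,
                     corrected=8, on_time=330, patients=23),
        "promis8": dict(weeks=21, responded=7, received=7, valid=7, corrected=0, patients=21),
    },
    "outpatient": {
        "pain": dict(query_days=359, compliant_days=327, received=595, valid=592,
                     corrected=14, on_time=423, patients=18),
        "attendance": dict(query_days=90, compliant_days=69, received=69, valid=69,
                           corrected=0, on_time=56, patients=5),
        "promis8": dict(weeks=54, responded=36, received=45, valid=44, corrected=4, patients=18),
    },
}

_VALID_TEXT = {"pain": "P2CHEST&3BELLY", "attendance": "WD", "promis8": "01324101"}
_INVALID_TEXT = {"pain": "2CHEST", "attendance": "WX", "promis8": "0132410"}
_BASE = datetime(2026, 1, 5, 13, 0, tzinfo=UTC)  # 08:00 America/New_York


def _daily_events(prefix: str, template_id: str, n_patients: int, total_days: int,
                  window_hours: float = 2.0) -> List[ReportEvent]:
    """One query event per patient-day, days split as evenly as possible."""
    base_days, extra = divmod(total_days, n_patients)
    events = []
    for i in range(n_patients):
        pid = f"{prefix}{i + 1:02d}"
        for d in range(base_days + (1 if i < extra else 0)):
            ws = _BASE + timedelta(days=d)
            events.append(
                ReportEvent(
                    window_start=ws,
                    window_end=ws + timedelta(hours=window_hours),
                    event_id=f"{pid}/{template_id}/{ws:%Y-%m-%dT%H:%M}",
                    patient_id=pid,
                    template_id=template_id,
                    reminder_offsets=(timedelta(minutes=60),) if window_hours >= 2 else (),
                )
            )
    return events


def _reconstruct_template(
    events: List[ReportEvent], template_id: str, counts: dict
) -> List[MessageLogEntry]:
    """Place valid/invalid entries on *events* to hit the marginal tallies."""
    n_valid = counts["valid"]
    n_invalid_uncorrected = counts["received"] - counts["valid"]
    n_corrected = counts["corrected"]
    n_on_time = counts.get("on_time", counts["valid"])
    n_compliant = counts.get("compliant_days", counts.get("responded"))
    compliant_events = events[:n_compliant]
    silent_events = events[n_compliant:]
    if len(silent_events) < n_invalid_uncorrected:
        raise ValueError("not enough silent query days to host uncorrected invalids")

    # every compliant day gets one valid message; extras round-robin on top
    hosts = list(compliant_events)
    for i in range(n_valid - n_compliant):
        hosts.append(compliant_events[i % n_compliant])
    valid_text = _VALID_TEXT[template_id]
    invalid_text = _INVALID_TEXT[template_id]
    log: List[MessageLogEntry] = []
    for i, ev in enumerate(hosts):
        on_time = i < n_on_time
        if on_time:
            at = ev.window_start + timedelta(minutes=30)
        else:
            at = ev.window_end + timedelta(minutes=30)
        corrected = i < n_corrected
        if corrected:
            log.append(
                MessageLogEntry(
                    patient_id=ev.patient_id, direction="inbound",
                    at=at - timedelta(minutes=5), raw_text=invalid_text,
                    classification="invalid", event_id=ev.event_id, template_id=template_id,
                )
            )
        log.append(
            MessageLogEntry(
                patient_id=ev.patient_id, direction="inbound", at=at, raw_text=valid_text,
                classification="valid", event_id=ev.event_id, template_id=template_id,
                corrected=corrected,
            )
        )
    # uncorrected invalid attempts live on otherwise-silent query days
    for ev in silent_events[:n_invalid_uncorrected]:
        log.append(
            MessageLogEntry(
                patient_id=ev.patient_id, direction="inbound",
                at=ev.window_start + timedelta(minutes=45), raw_text=invalid_text,
                classification="invalid", event_id=ev.event_id, template_id=template_id,
            )
        )
    return log


def reconstruct_pilot_log() -> Tuple[List[ReportEvent], List[MessageLogEntry], Dict[str, str]]:
    """Deterministic synthetic log matching a pilot trial's marginal counts.

    Returns ``(events, log, settings)`` where *settings* maps each synthetic
    patient id to its setting.  The statistics layer applied to this log
    reproduces every printed ratio exactly (e.g. inpatient pain compliance
    112/118, validity 378/383, on-time 330/378; outpatient on-time 423/595
    over received; weekly scale compliance 7/21 and 36/54; scale validity
    44/45), because those ratios are fully determined by the tallies.
    """
    events: List[ReportEvent] = []
    log: List[MessageLogEntry] = []
    settings: Dict[str, str] = {}
    for setting, prefix in (("inpatient", "ip"), ("outpatient", "op")):
        for template_id, counts in PILOT_COUNTS[setting].items():
            if template_id == "promis8":
                evs = _weekly_events(prefix, counts["patients"], counts["weeks"])
            else:
                evs = _daily_events(prefix, template_id, counts["patients"],
                                    counts["query_days"])
            events.extend(evs)
            log.extend(_reconstruct_template(evs, template_id, counts))
            for ev in evs:
                settings[ev.patient_id] = setting
    events.sort()
    log.sort(key=lambda e: (e.at, e.patient_id, e.classification))
    return events, log, settings


def _weekly_events(prefix: str, n_patients: int, total_weeks: int) -> List[ReportEvent]:
    """One weekend scale window (Friday 18:00 -> Sunday 21:00 local) per query week."""
    base_weeks, extra = divmod(total_weeks, n_patients)
    events = []
    friday = datetime(2026, 1, 9, 23, 0, tzinfo=UTC)  # Fri 18:00 America/New_York
    for i in range(n_patients):
        pid = f"{prefix}{i + 1:02d}"
        for w in range(base_weeks + (1 if i < extra else 0)):
            ws = friday + timedelta(weeks=w)
            events.append(
                ReportEvent(
                    window_start=ws,
                    window_end=ws + timedelta(hours=51),
                    event_id=f"{pid}/promis8/{ws:%Y-%m-%dT%H:%M}",
                    patient_id=pid,
                    template_id="promis8",
                    reminder_offsets=(timedelta(hours=24),),
                )
            )
    return events
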