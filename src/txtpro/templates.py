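"""Declarative report templates and the structured-message grammar.

Adolescent patients self-report via plain SMS text using compact, fixed
formats instead of free text: a pain report is a header ``P`` followed by
``<intensity><LOCATION>`` pairs joined by ``&`` (``P2CHEST&3BELLY``; ``PN``
for no pain), school attendance is one of four two-letter codes, and a
multi-item scale answer is a fixed-length digit string (``01324101`` for an
8-item 0-4 scale).  Every template is described by a :class:`TemplateSpec`;
parsing either yields a typed report or exactly one error code plus an
error-proofing instruction that embeds a valid example, so the patient can
correct the message in real time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class ErrorCode(str, Enum):
    """Single-cause classification of an invalid inbound report."""

    bad_header = "bad_header"
    unknown_location = "unknown_location"
    intensity_out_of_range = "intensity_out_of_range"
    duplicate_location = "duplicate_location"
    bad_code = "bad_code"
    wrong_length = "wrong_length"
    digit_out_of_range = "digit_out_of_range"
    empty = "empty"
    trailing_garbage = "trailing_garbage"


@dataclass(frozen=True)
class PainReport:
    """Ordered (intensity, location) pairs; ``no_pain`` iff pairs is empty."""

    pairs: Tuple[Tuple[int, str], ...]
    no_pain: bool = False

    def __post_init__(self) -> None:
        if self.no_pain != (len(self.pairs) == 0):
            raise ValueError("no_pain must hold exactly when pairs is empty")
        locations = [loc for _, loc in self.pairs]
        if len(set(locations)) != len(locations):
            raise ValueError("duplicate pain location in report")


@dataclass(frozen=True)
class AttendanceReport:
    code: str


@dataclass(frozen=True)
class ScaleReport:
    items: Tuple[int, ...]


ParsedReport = Union[PainReport, AttendanceReport, ScaleReport]


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of parsing one inbound message against a template.

    ``valid`` holds exactly when ``report`` is present and ``error_code``
    absent; an invalid result always carries the error-proofing
    ``instruction`` (which embeds the template's valid example).
    """

    valid: bool
    report: Optional[ParsedReport] = None
    error_code: Optional[ErrorCode] = None
    instruction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.valid != (self.report is not None) or self.valid != (self.error_code is None):
            raise ValueError("valid <=> report present <=> error_code absent")
        if not self.valid and not self.instruction:
            raise ValueError("invalid result requires an instruction")


class TemplateSpec(BaseModel):
    """Declarative grammar for one report type.

    ``kind`` selects the grammar family:

    - ``pair_list``: header + ``&``-joined intensity/location pairs, with an
      optional whole-message no-event code (``no_event_response``).
    - ``code_choice``: the message is exactly one code from ``code_options``.
    - ``digit_vector``: exactly ``item_count`` digits, each in ``item_range``.
    """

    model_config = ConfigDict(frozen=True)

    template_id: str
    kind: Literal["pair_list", "code_choice", "digit_vector"]
    header: str = ""
    intensity_range: Optional[Tuple[int, int]] = None
    location_vocabulary: Optional[Tuple[str, ...]] = None
    code_options: Optional[Tuple[str, ...]] = None
    item_count: Optional[int] = None
    item_range: Optional[Tuple[int, int]] = None
    no_event_response: Optional[str] = None
    valid_example: str

    @field_validator("location_vocabulary", "code_options")
    @classmethod
    def _codes_uppercase_alpha(cls, v):
        if v is None:
            return v
        for code in v:
            if not code or not code.isalpha() or code != code.upper():
                raise ValueError(f"code {code!r} must be non-empty uppercase alphabetic")
        if len(set(v)) != len(v):
            raise ValueError("duplicate codes in vocabulary")
        return tuple(v)

    @model_validator(mode="after")
    def _check_kind_fields(self):
        if self.kind == "pair_list":
            if self.intensity_range is None or self.location_vocabulary is None:
                raise ValueError("pair_list requires intensity_range and location_vocabulary")
            lo, hi = self.intensity_range
            if lo > hi:
                raise ValueError("intensity_range must be non-decreasing")
            # prefix-freedom guarantees unambiguous tokenization
            vocab = self.location_vocabulary
            for a in vocab:
                for b in vocab:
                    if a != b and b.startswith(a):
                        raise ValueError(f"location code {a!r} is a prefix of {b!r}")
        elif self.kind == "code_choice":
            if not self.code_options:
                raise ValueError("code_choice requires code_options")
        elif self.kind == "digit_vector":
            if not self.item_count or self.item_count < 1 or self.item_range is None:
                raise ValueError("digit_vector requires item_count >= 1 and item_range")
            lo, hi = self.item_range
            if not (0 <= lo <= hi <= 9):
                raise ValueError("item_range must lie within single digits 0..9")
        result = parse(self.valid_example, self)
        if not result.valid:
            raise ValueError(
                f"valid_example {self.valid_example!r} does not parse: {result.error_code}"
            )
        return self


# ---------------------------------------------------------------------------
# Parsing

_PAIR_RE = re.compile(r"(\d+)([A-Z]+)\Z")


def _invalid(spec: TemplateSpec, code: ErrorCode) -> ValidationResult:
    return ValidationResult(
        valid=False, error_code=code, instruction=error_instruction(spec, code)
    )


def _parse_pair_list(text: str, spec: TemplateSpec) -> ValidationResult:
    ner = spec.no_event_response
    if ner is not None:
        if text == ner:
            return ValidationResult(valid=True, report=PainReport(pairs=(), no_pain=True))
        if text.startswith(ner) and not text[len(ner):][:1].isdigit():
            # e.g. "PN&2HEAD": the no-event code must be the whole message
            return _invalid(spec, ErrorCode.trailing_garbage)
    if spec.header and not text.startswith(spec.header):
        return _invalid(spec, ErrorCode.bad_header)
    body = text[len(spec.header):]
    if not body:
        return _invalid(spec, ErrorCode.trailing_garbage)
    lo, hi = spec.intensity_range
    seen: set[str] = set()
    pairs = []
    for token in (t.strip() for t in body.split("&")):
        if not token:
            return _invalid(spec, ErrorCode.trailing_garbage)
        m = _PAIR_RE.fullmatch(token)
        if m is None:
            return _invalid(spec, ErrorCode.trailing_garbage)
        intensity, location = int(m.group(1)), m.group(2)
        if not lo <= intensity <= hi:
            return _invalid(spec, ErrorCode.intensity_out_of_range)
        if location not in spec.location_vocabulary:
            return _invalid(spec, ErrorCode.unknown_location)
        if location in seen:
            return _invalid(spec, ErrorCode.duplicate_location)
        seen.add(location)
        pairs.append((intensity, location))
    return ValidationResult(valid=True, report=PainReport(pairs=tuple(pairs)))


def _parse_code_choice(text: str, spec: TemplateSpec) -> ValidationResult:
    if text in spec.code_options:
        return ValidationResult(valid=True, report=AttendanceReport(code=text))
    return _invalid(spec, ErrorCode.bad_code)


def _parse_digit_vector(text: str, spec: TemplateSpec) -> ValidationResult:
    if not text.isdigit():
        return _invalid(spec, ErrorCode.bad_code)
    if len(text) != spec.item_count:
        return _invalid(spec, ErrorCode.wrong_length)
    lo, hi = spec.item_range
    items = tuple(int(c) for c in text)
    if any(not lo <= d <= hi for d in items):
        return _invalid(spec, ErrorCode.digit_out_of_range)
    return ValidationResult(valid=True, report=ScaleReport(items=items))


def parse(text: str, spec: TemplateSpec) -> ValidationResult:
    """Parse a raw inbound message against *spec*.

    Matching is case-insensitive with surrounding whitespace tolerated; valid
    reports are stored canonically uppercase.  Each grammar violation maps to
    exactly one :class:`ErrorCode`; the first violation left-to-right wins.
    """
    canonical = text.strip().upper()
    if not canonical:
        return _invalid(spec, ErrorCode.empty)
    if spec.kind == "pair_list":
        return _parse_pair_list(canonical, spec)
    if spec.kind == "code_choice":
        return _parse_code_choice(canonical, spec)
    return _parse_digit_vector(canonical, spec)


def render(report: ParsedReport, spec: TemplateSpec) -> str:
    """Canonical uppercase message for a valid report; parse(render(r)) == r."""
    if isinstance(report, PainReport):
        if report.no_pain:
            if spec.no_event_response is None:
                raise ValueError("template has no no-event response code")
            return spec.no_event_response
        return spec.header + "&".join(f"{i}{loc}" for i, loc in report.pairs)
    if isinstance(report, AttendanceReport):
        return report.code
    if isinstance(report, ScaleReport):
        return "".join(str(d) for d in report.items)
    raise TypeError(f"unknown report type {type(report)!r}")


# ---------------------------------------------------------------------------
# Error-proofing instructions

def _rule_text(spec: TemplateSpec, code: ErrorCode) -> str:
    if spec.kind == "pair_list":
        lo, hi = spec.intensity_range
        locations = ", ".join(spec.location_vocabulary)
        rules = {
            ErrorCode.bad_header: f"Your report must start with '{spec.header}'.",
            ErrorCode.unknown_location: f"Use only these locations: {locations}.",
            ErrorCode.intensity_out_of_range: f"Each intensity must be a number from {lo} to {hi}.",
            ErrorCode.duplicate_location: "Report each location at most once.",
            ErrorCode.empty: "Your message was empty.",
            ErrorCode.trailing_garbage: (
                f"Send intensity/location pairs joined by '&' "
                f"(intensities {lo}-{hi}; locations: {locations})"
                + (f", or '{spec.no_event_response}' alone if there is nothing to report."
                   if spec.no_event_response else ".")
            ),
        }
        return rules.get(code, rules[ErrorCode.trailing_garbage])
    if spec.kind == "code_choice":
        options = ", ".join(spec.code_options)
        if code == ErrorCode.empty:
            return f"Your message was empty. Reply with one of: {options}."
        return f"Reply with exactly one of: {options}."
    lo, hi = spec.item_range
    base = f"Reply with exactly {spec.item_count} digits, each from {lo} to {hi}."
    if code == ErrorCode.empty:
        return "Your message was empty. " + base
    return base


def error_instruction(spec: TemplateSpec, error_code: ErrorCode) -> str:
    """Human-readable error-proofing reply naming the violated rule.

    Always embeds ``spec.valid_example`` so the patient can copy a working
    format, and asks them to resend.
    """
    return (
        f"Sorry, we could not read your report. {_rule_text(spec, error_code)} "
        f"For example: '{spec.valid_example}'. Please send your report again."
    )


# ---------------------------------------------------------------------------
# Built-in templates and template files

def _builtin(template_id: str, **kwargs) -> TemplateSpec:
    return TemplateSpec(template_id=template_id, **kwargs)


PAIN = _builtin(
    "pain",
    kind="pair_list",
    header="P",
    intensity_range=(1, 10),
    location_vocabulary=("HEAD", "CHEST", "BELLY", "BACK", "UL", "UR", "LL", "LR"),
    no_event_response="PN",
    valid_example="P2CHEST&3BELLY",
)
ATTENDANCE = _builtin(
    "attendance",
    kind="code_choice",
    code_options=("WD", "AM", "AF", "AW"),
    valid_example="WD",
)
PROMIS8 = _builtin(
    "promis8",
    kind="digit_vector",
    item_count=8,
    item_range=(0, 4),
    valid_example="01324101",
)


def builtin_templates() -> dict[str, TemplateSpec]:
    """The three shipped templates keyed by template_id."""
    return {t.template_id: t for t in (PAIN, ATTENDANCE, PROMIS8)}


def load_template(source: Union[str, Path]) -> TemplateSpec:
    """Load one TemplateSpec from a YAML file."""
    data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"{source}: template file must contain a mapping")
    return TemplateSpec(**data)


def load_template_dir(directory: Union[str, Path]) -> dict[str, TemplateSpec]:
    """Load every ``*.yaml`` template in *directory*, keyed by template_id."""
    specs = {}
    for path in sorted(Path(directory).glob("*.yaml")):
        spec = load_template(path)
        if spec.template_id in specs:
            raise ValueError(f"duplicate template_id {spec.template_id!r} in {directory}")
        specs[spec.template_id] = spec
    return specs


def shipped_template_dir() -> Path:
    """Directory of the YAML files for the three shipped templates."""
    return Path(resources.files("txtpro").joinpath("data", "templates"))
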