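"""Template grammar: parsing, rendering, error-proofing, and its invariants."""

from __future__ import annotations

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txtpro.templates import (
    ATTENDANCE,
    PAIN,
    PROMIS8,
    AttendanceReport,
    ErrorCode,
    PainReport,
    ScaleReport,
    TemplateSpec,
    builtin_templates,
    error_instruction,
    load_template,
    load_template_dir,
    parse,
    render,
    shipped_template_dir,
)

LOCATIONS = PAIN.location_vocabulary


# ---------------------------------------------------------------------------
# Worked examples

@pytest.mark.parametrize(
    "text,pairs,no_pain",
    [
        ("P2CHEST&3BELLY", ((2, "CHEST"), (3, "BELLY")), False),
        ("PN", (), True),
        ("P10BACK&1UL", ((10, "BACK"), (1, "UL")), False),
        ("p2chest&3belly", ((2, "CHEST"), (3, "BELLY")), False),
        ("  P4HEAD  ", ((4, "HEAD"),), False),
        ("P1HEAD&2CHEST&3BELLY&4BACK&5UL&6UR&7LL&8LR",
         ((1, "HEAD"), (2, "CHEST"), (3, "BELLY"), (4, "BACK"),
          (5, "UL"), (6, "UR"), (7, "LL"), (8, "LR")), False),
    ],
)
def test_pain_valid_messages(text, pairs, no_pain):
    result = parse(text, PAIN)
    assert result.valid
    assert result.report == PainReport(pairs=pairs, no_pain=no_pain)


@pytest.mark.parametrize(
    "text,error_code",
    [
        ("P0HEAD", ErrorCode.intensity_out_of_range),
        ("P11HEAD", ErrorCode.intensity_out_of_range),
        ("P2CHEST&4CHEST", ErrorCode.duplicate_location),
        ("2CHEST", ErrorCode.bad_header),
        ("P2NOSE", ErrorCode.unknown_location),
        ("PN&2HEAD", ErrorCode.trailing_garbage),
        ("P2CHEST&", ErrorCode.trailing_garbage),
        ("P", ErrorCode.trailing_garbage),
        ("PCHEST", ErrorCode.trailing_garbage),
        ("", ErrorCode.empty),
        ("   ", ErrorCode.empty),
        # first violation left-to-right wins
        ("P2CHEST&0NOSE", ErrorCode.intensity_out_of_range),
        ("P0NOSE&2CHEST", ErrorCode.intensity_out_of_range),
    ],
)
def test_pain_invalid_messages(text, error_code):
    result = parse(text, PAIN)
    assert not result.valid
    assert result.error_code == error_code
    assert PAIN.valid_example in result.instruction


@pytest.mark.parametrize(
    "text,expected",
    [("WD", "WD"), ("aw", "AW"), (" am ", "AM"), ("AF", "AF")],
)
def test_attendance_valid(text, expected):
    result = parse(text, ATTENDANCE)
    assert result.valid and result.report == AttendanceReport(code=expected)


@pytest.mark.parametrize("text", ["WX", "W", "WDX", "YES", "1"])
def test_attendance_invalid(text):
    result = parse(text, ATTENDANCE)
    assert result.error_code == ErrorCode.bad_code
    for option in ATTENDANCE.code_options:
        assert option in result.instruction


@pytest.mark.parametrize(
    "text,outcome",
    [
        ("01324101", (0, 1, 3, 2, 4, 1, 0, 1)),
        ("00000000", (0, 0, 0, 0, 0, 0, 0, 0)),
        ("0132410", ErrorCode.wrong_length),
        ("013241011", ErrorCode.wrong_length),
        ("01324105", ErrorCode.digit_out_of_range),
        ("0132410a", ErrorCode.bad_code),
    ],
)
def test_scale_parsing(text, outcome):
    result = parse(text, PROMIS8)
    if isinstance(outcome, tuple):
        assert result.valid and result.report == ScaleReport(items=outcome)
    else:
        assert result.error_code == outcome


def test_error_instruction_names_the_rule():
    text = error_instruction(PAIN, ErrorCode.intensity_out_of_range)
    assert "P2CHEST&3BELLY" in text and "1" in text and "10" in text
    text = error_instruction(PROMIS8, ErrorCode.wrong_length)
    assert "8 digits" in text and PROMIS8.valid_example in text


# ---------------------------------------------------------------------------
# Spec validation

def test_template_spec_rejects_bad_vocabulary():
    with pytest.raises(ValueError, match="uppercase"):
        TemplateSpec(template_id="x", kind="code_choice", code_options=("wd",), valid_example="wd")
    with pytest.raises(ValueError, match="prefix"):
        TemplateSpec(
            template_id="x", kind="pair_list", header="P", intensity_range=(1, 10),
            location_vocabulary=("UL", "ULX"), valid_example="P2UL",
        )
    with pytest.raises(ValueError, match="does not parse"):
        TemplateSpec(
            template_id="x", kind="digit_vector", item_count=4, item_range=(0, 4),
            valid_example="99999",
        )


def test_shipped_template_files_match_builtins():
    loaded = load_template_dir(shipped_template_dir())
    assert loaded == builtin_templates()


# ---------------------------------------------------------------------------
# Property: round trip over the full grammar

pain_reports = st.lists(
    st.sampled_from(LOCATIONS), min_size=0, max_size=len(LOCATIONS), unique=True
).flatmap(
    lambda locs: st.tuples(*(st.integers(1, 10) for _ in locs)).map(
        lambda intensities: PainReport(
            pairs=tuple(zip(intensities, locs)), no_pain=not locs
        )
    )
)
scale_reports = st.lists(st.integers(0, 4), min_size=8, max_size=8).map(
    lambda items: ScaleReport(items=tuple(items))
)
attendance_reports = st.sampled_from(ATTENDANCE.code_options).map(
    lambda c: AttendanceReport(code=c)
)


@settings(derandomize=True, max_examples=300)
@given(
    report_spec=st.one_of(
        pain_reports.map(lambda r: (r, PAIN)),
        scale_reports.map(lambda r: (r, PROMIS8)),
        attendance_reports.map(lambda r: (r, ATTENDANCE)),
    )
)
def test_round_trip(report_spec):
    report, spec = report_spec
    result = parse(render(report, spec), spec)
    assert result.valid and result.report == report


# ---------------------------------------------------------------------------
# Property: rejection completeness under single-character mutation

_ALPHABET = "PNWDAMFUW0123456789&XHEADCHESTBELLYBACKULURLLLR abz!"


@settings(derandomize=True, max_examples=300)
@given(
    report=pain_reports,
    position=st.integers(0, 30),
    op=st.sampled_from(["insert", "delete", "substitute"]),
    char=st.sampled_from(_ALPHABET),
)
def test_rejection_completeness(report, position, op, char):
    """Any single-character mutation yields either a valid parse or exactly
    one error code -- never a crash, never silent acceptance of an
    out-of-range value."""
    text = render(report, PAIN)
    i = position % (len(text) + (op == "insert"))
    if op == "insert":
        mutated = text[:i] + char + text[i:]
    elif op == "delete":
        mutated = text[:i] + text[i + 1:] if text else text
    else:
        mutated = text[:i] + char + text[i + 1:] if text else char
    result = parse(mutated, PAIN)
    if result.valid:
        for intensity, location in result.report.pairs:
            assert 1 <= intensity <= 10 and location in LOCATIONS
    else:
        assert isinstance(result.error_code, ErrorCode)
        assert PAIN.valid_example in result.instruction


# ---------------------------------------------------------------------------
# Property: case/whitespace insensitivity

@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet=_ALPHABET.lower() + _ALPHABET, max_size=20))
def test_case_and_whitespace_insensitive(text):
    for spec in (PAIN, ATTENDANCE, PROMIS8):
        a, b = parse(text, spec), parse(text.upper().strip(), spec)
        assert (a.valid, a.report, a.error_code) == (b.valid, b.report, b.error_code)


# ---------------------------------------------------------------------------
# Prefix-freedom => unique tokenization (independent brute-force oracle)

def brute_force_pain_parses(text: str):
    """Enumerate every digit/code split of every '&' token; return all parses
    accepted under the grammar, independently of the production parser."""
    if not text.startswith("P"):
        return []
    parses = []

    def token_splits(token):
        return [
            (int(token[:i]), token[i:])
            for i in range(1, len(token))
            if token[:i].isdigit() and 1 <= int(token[:i]) <= 10 and token[i:] in LOCATIONS
        ]

    tokens = text[1:].split("&")
    options = [token_splits(t) for t in tokens]
    if all(options):
        from itertools import product

        for combo in product(*options):
            locs = [loc for _, loc in combo]
            if len(set(locs)) == len(locs):
                parses.append(tuple(combo))
    return parses


@pytest.mark.parametrize("text", ["P10BACK&1UL", "P2CHEST&3BELLY", "P1UL&10LR&2HEAD"])
def test_tokenization_is_unique(text):
    parses = brute_force_pain_parses(text)
    assert len(parses) == 1
    assert parse(text, PAIN).report.pairs == parses[0]


@settings(derandomize=True, max_examples=200)
@given(report=pain_reports)
def test_unique_parse_over_random_valid_messages(report):
    if report.no_pain:
        return
    text = render(report, PAIN)
    parses = brute_force_pain_parses(text)
    assert len(parses) == 1 and parses[0] == report.pairs
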