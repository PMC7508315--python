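# Methods

## The reporting model

`txtpro` models structured self-reporting over SMS as four cooperating
pieces: a template grammar, a schedule of query windows, a conversation
loop with real-time error-proofing, and an outcome-statistics layer. The
design assumption throughout is that every report fits in one message and
every message is machine-checkable: the system never interprets free text,
it only accepts or rejects against a declared template and teaches the
sender the format when rejecting.

### Template grammar

A `TemplateSpec` declares one of three grammar families:

- `pair_list` — an optional header, then `&`-joined
  `<intensity><LOCATION>` tokens. Digits are consumed greedily before the
  alphabetic location code, which makes two-digit intensities (`10`)
  unambiguous because location codes never begin with a digit. The
  location vocabulary must be prefix-free; together with the explicit `&`
  separator this guarantees a unique tokenization, which the test suite
  verifies against a brute-force enumerator of all digit/code split
  points. Duplicate locations are rejected rather than last-wins: forcing
  a restatement is consistent with the error-proofing philosophy. A
  whole-message no-event code (`PN`) reports the absence of the symptom;
  it must be the entire message (`PN&2HEAD` is `trailing_garbage`).
- `code_choice` — the message is exactly one code from a closed set.
- `digit_vector` — exactly `item_count` digits, each inside `item_range`.

Parsing is case-insensitive with surrounding whitespace tolerated
(adolescents text in mixed case); storage is canonical uppercase, and
`parse(render(r)) == r` is a tested invariant over the full grammar.
Every failure maps to exactly one error code, first violation
left-to-right. Two taxonomy details the printed format leaves open were
fixed as follows: a pair token with no leading digits, or with leftover
characters after its location code, is `trailing_garbage`; within a
token the intensity is checked before the location (so `0XYZ` is
`intensity_out_of_range`). In the digit-vector family non-digit
characters are reported (`bad_code`) before length, and length before
range.

The error instruction always embeds the template's `valid_example` and
names the violated rule; `valid_example` is itself validated at spec
construction, so an instruction can never teach a broken format.

### Scheduling

Schedules are defined in the patient's local clock (IANA timezone) as
daily or weekly recurrences with a window length in minutes; expansion
over a horizon produces UTC events. Windows are fixed spans of absolute
time anchored at the configured local clock time, so daylight-saving
transitions shift the UTC instant, never the local prompt time (tested on
a spring-forward boundary). Exception dates (school breaks) are skipped
at expansion.

Defaults, all configurable per patient: inpatients get three 2-hour pain
windows at 08:00, 12:00 and 17:00 local — three chances inside
07:00–19:00, interpreted as three independent windows rather than one
window with three reminders (daily compliance, requiring at least one
report per day, is identical either way); outpatients additionally get a
dinnertime (18:00) attendance window; both get a weekly scale window from
Friday 19:00 to Sunday 21:00 and a daily one-way health tip. The default
reminder policy is one reminder at the window midpoint. The weekly prompt
sits at 19:00 with reminders at +25 h/+49 h so that no two initial
prompts of different templates coincide.

On-time means inside the closed interval `[window_start, window_end]`.
Latency is measured from the initial prompt (= window start), the only
anchor defined for every event, and is aggregated over on-time valid
messages only. Late valid reports are recorded, count toward compliance,
and simply fail the on-time predicate.

Schedules round-trip through a deliberately small iCalendar (RFC 5545)
subset — one `VEVENT` per recurrence with `DTSTART;TZID`, `DURATION`,
`RRULE` (`FREQ=DAILY`/`FREQ=WEEKLY;BYDAY=..`), `EXDATE` and private
`X-TXTPRO-*` properties for the template binding. The writer/reader
lives in-package and is tested by re-expansion equality and byte-stable
re-serialization; it is not a general iCalendar consumer.

### Conversation loop

The engine keeps one pending query per patient (set by the initial
prompt). An inbound message is parsed against the pending template first;
if it instead parses under another template it is attributed to the most
recent event of that template whose window has opened — this is what lets
a late pain report or an attendance code sent during the weekend scale
window land on the right query, because the three shipped grammars are
mutually exclusive on valid strings. A message that parses under nothing
while a query is pending gets that template's error instruction and
increments the attempt count (no cap on retries); with nothing pending it
gets a generic help reply and is logged as `other`, never stored.

A valid report is stored with `corrected = (an invalid attempt preceded
it on the same pending query)`. Only digit-vector (scale) reports are
resubmittable: a second valid answer within the window supersedes the
stored one (last write wins) while both raw messages stay in the log; a
resend after the window closes is logged but not applied. Pain and
attendance duplicates within a window are stored as additional reports.

Known limitation: when two queries of different templates are pending in
overlapping windows, an *invalid* message cannot be attributed by content
and is charged to the currently pending query. With the default
protocols this requires an unusually slow reply plus a format error in
the same exchange; simulations needing exact corrected-count accounting
restrict the protocol to one template (the `templates` profile field).

Threshold alarms fire when a stored pain report's score strictly exceeds
the patient's threshold ("above the threshold" read as strict; the
worked rule — threshold 5, score 6 alarms — is satisfied). The score of
a multi-site report is the maximum intensity, the clinically conservative
aggregation; a no-pain report scores 0. Alarms are defined for pain only.

### Message pools

"Don't repeat yourself" is formalized as shuffled-cycle selection: per
patient, a random permutation of the pool is consumed; on exhaustion it
reshuffles, forbidding an immediate repeat across the boundary when the
pool has more than one message. Within a cycle every message appears
exactly once, and long-run frequencies are uniform (chi-square checked).
Pool files are plain UTF-8 text with `[subset]` headers, one message per
line; empty subsets and duplicates are load errors. The shipped tip pool
(11 subsets, 54 messages) is synthetic fixture text.

### Statistics

The collapse rule for "received messages" is the one consistent with
trial tables that report corrected messages as a subset of valid ones:
walking an event's inbound entries in time order, each valid entry is one
received message, and a trailing run of invalid attempts never followed
by a valid entry is one received invalid message. Raw attempts remain in
the log. A "query day" is a patient-local calendar day with at least one
scheduled query of the template; each expanded weekly event is one query
week. Published tables have printed on-time rates over both valid and
received denominators, so both variants are computed and labelled
(`on_time_pct`, `on_time_over_received_pct`), defaulting to over-valid.
Undefined statistics (zero denominators) are `None`, never 0.

Exports (reports, message log, summary) write a fixed whitelist of
columns keyed by opaque patient identifiers; no display-name directory
kept by a caller can reach a file, and CSV export → import → export is
byte-identical.

## The cohort simulator

The simulator emulates an engaged adolescent cohort, not sickle-cell
biology. Per two-way event: respond with probability 0.95; latency
log-normal with median 30 min and σ = 0.6 (motivated by observed mean
response times in the half-hour range — a shape choice, not a fit); with
probability 0.02 the first message is a random grammar-breaking mutation
(drop header, out-of-range digit, unknown code, wrong length — re-parsed
to guarantee failure), followed with probability 0.8 by the corrected
valid message 1–10 min later. Enrollment defaults: 5 days inpatient, 20
outpatient. The pain content process (60% pain days, geometric site
count capped at 8, uniform intensities) and the attendance/scale
distributions are plain fixtures. Ground truth (intended classification
per generated message) is emitted alongside the traffic so tests never
re-derive labels from the engine under test. Identical config and seed
give byte-identical logs.

What passing simulator-based tests shows: the engine, scheduler and
statistics agree with each other and with the generating parameters
(e.g. observed compliance within three binomial standard errors of the
response probability over ≥3000 events). What it does not show: anything
about real adolescent behaviour — real latencies are heavy-tailed and
schedule-dependent, real errors are not uniform over mutation kinds, and
real compliance decays over time.

`reconstruct_pilot_log` is different in kind: a deterministic synthetic
log whose marginal counts equal a published pilot's tallies (118/112
inpatient pain days, 383/378/8/330 messages, 359/327 and 595/592/14/423
outpatient, 90/69/56 attendance, 21/7 and 54/36/45/44 weekly-scale). How
the messages are placed on days is arbitrary (round-robin, fixed 30-min
latencies); every reported ratio is invariant to that placement because
it is fully determined by the tallies. It exists to verify the
statistics layer against printed percentages, and mean latencies are
deliberately *not* treated as reproducible from it, since they depend on
raw timestamps no table prints.

## Numerical and problem-size choices

All rates are exact rational arithmetic on counts; percentages are
rounded to one decimal only at presentation. The default test run keeps
simulations small (cohorts of ≤30, horizons of ≤100 days, ~10^3–10^4
messages), which the statistics tolerances are sized for; everything is
seeded, including hypothesis (derandomized), so runs are reproducible.
Seeds derived inside the package stay below 2^31.

## Known limitations

- The engine trusts message timestamps; carrier delays, message loss and
  delivery receipts are out of scope (the transport is an abstract
  `(patient_id, text, timestamp)` contract).
- One pending query per patient (see the attribution limitation above).
- Thresholds apply to pain scores only; weekly-scale totals do not alarm.
- The iCalendar support is the subset the package itself writes.
- Instruction and prompt text is English-only.
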