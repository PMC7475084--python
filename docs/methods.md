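# Methods

## Scope and data model

`rxdur` analyses longitudinal prescription data for one index drug (role
`LDX`) against a background of other ADHD medication (`MPH`, `ATX`,
`other_ADHD`) and unrelated co-medication (`non_ADHD`). Drugs are roles:
a schema config maps source vocabularies (e.g. ATC codes) onto them, so
nothing in the machinery is specific to a product name.

Dates are ISO calendar dates; every interval is closed–open `[start, end)`
in whole days. Ages are year-granular (`event year − birth year`), which
is what prescription registries typically expose; the package never
assumes exact birth dates. Three event tables travel between stages —
patients, prescriptions, diagnoses — as UTF-8 delimited text, and
validation is conservation-based: each input row is loaded, coerced, or
rejected into a log carrying the file, 1-based line number and reason.

## Coverage and episodes

A prescription's coverage length is, in order of precedence: the recorded
days' supply; `quantity × strength ÷ daily instruction`, rounded to the
nearest whole day with a 1-day floor; a configurable default (30 days).
The daily dose is the recorded instruction, else total mg spread over the
interval; with neither instruction nor quantity × strength the dose is
unknown (NaN) and propagates to a not-evaluable dose audit rather than a
silently wrong one.

Overlap handling is *stockpiling* by default: a refill issued before the
previous supply ends has its coverage deferred to start at the running
coverage end, so dispensed days and milligrams are conserved through
episode merging (an invariant the tests enforce). The alternative
`truncate` policy clips the overlapped supply instead; it is exposed
because some analyses prefer it, but conservation is the defensible
default when nothing is known about actual consumption.

Episodes merge intervals whose issue date is at most `gap_days` after the
running coverage end. The 30-day grace period is a single global
parameter shared by episode construction, discontinuation and switching,
because all three definitions use the same window; an analysis that
varied them independently would be incoherent at the boundaries.

Duration of exposure is reported as the **sum of episode spans** (first
issue to end of final coverage, per episode). The alternative — first
issue to last coverage end across all episodes — is also emitted
(`overall_span_days`) but not headlined: if a >30-day gap is long enough
to end an episode, it should not count as exposure time.

## Pattern definitions and numerical choices

All pattern windows are anchored at prescription-period **ends** (coverage
ends after overlap resolution), not issue dates. `boundary="inclusive"`
(default) means an event exactly `gap_days` after an end is inside the
window: a 30-day gap continues an episode and counts as a switch; 31 days
does not. The exclusive convention is available and covered by tests.

* **Discontinuation** is flagged at any index-drug episode end with no
  ADHD-medication issue within the window, provided the window is fully
  observed (`end + gap ≤ window end`). The patient-level headline is
  *ever discontinued*, so a mid-history break followed by re-initiation
  counts; the first qualifying date is reported. Whether re-initiators
  should count is genuinely open in the field; flag-per-episode-end plus
  an "ever" rollup keeps both readings recoverable from the patient table.
* **Censoring**: a patient whose final episode end has an incompletely
  observed window and no event is censored, not discontinued. Because
  some analyses ignore this, the unadjudicated count
  (`discontinued_naive`) is reported alongside.
* **Switching** scans all (period end, cross-drug issue) pairs within a
  patient. An index issue during another drug's ongoing coverage is
  co-prescription, not a switch; it is flagged separately
  (`overlap_initiation`) and counts as a switch only if it also falls
  within the window after some period end of that drug.
* At a single episode end, switch evidence and discontinuation are
  mutually exclusive by construction; a patient can still carry both
  flags from different episode ends.

Degenerate inputs: empty tables yield empty, typed outputs at every
stage; a prescription with no basis for a coverage length and no default
raises with the offending rows; `gap_days < 0` is rejected.

## Off-label rule engine

Criteria follow the paediatric label of the index drug (second-line after
MPH, ages 6+, ≤70 mg/day) plus jurisdiction-specific adult provisions
with effective dates. Choices the rules had to fix:

* *Prior diagnosis* is strictly before the first index prescription; the
  demographic "documented diagnosis" measure uses at-or-before.
* *Prior MPH* is evaluable only with ≥365 days of enrolment history
  before the first index prescription — a shorter lookback cannot
  distinguish "no prior use" from "use before enrolment".
* *Dose*: the headline flag uses the patient-level average daily dose
  (the cap is defined per day of use, and the conventional dose statistic
  is computed for patients within the cap); a stricter per-prescription
  variant (`any_rx_dose_exceeds_cap`) is computed alongside because the
  phrase "prescribed dosage exceeding the maximum" admits both readings.
* *Adult use* (age ≥ 19) is on-label when an adult approval is in force
  at the issue date (with an optional age cap, 55 in Switzerland), or
  when the prescription's episode began before the adult threshold —
  continuation from adolescence reuses the same 30-day chain rule, since
  any gap ≤ 30 days is by definition the same episode.
* Flags are tri-state (`True`/`False`/`NA`); a not-evaluable criterion
  never contributes to `any_off_label`. Sources that record no diagnoses
  (Swiss pharmacy panels) make criterion 1 not-evaluable; sources without
  ages (the self-dispensing panel) disable the age-based criteria.
* Denmark's adult approval arrived mid-window (January 2015), so a single
  whole-window adult-off-label figure is not reportable; the config masks
  it in summaries (`report_adult_off_label=False`) while the per-patient
  flag remains available for auditing.

Monotonicity holds by construction and is tested: moving the adult
approval date earlier never increases the off-label count; raising
`gap_days` never increases episode or discontinuation counts.

## Synthetic cohort generator

The generator stands in for inaccessible registries. Per patient it
draws sex, an age band, a source profile, then a first index prescription
date uniform over the country's observation window; optionally an ADHD
diagnosis (probability `p_adhd_recorded`) and a prior-MPH chain placed
either within the 30-day switch window before the first index issue or
beyond it; then a refill sequence with per-refill competing hazards of
stopping (`discontinuation_hazard`) and switching (`switch_hazard`), and
refill gaps from a two-component mixture: on-time gaps uniform on
[0, 30] days and, with probability `p_late_refill`, late gaps of
31 + Exponential(60) days (capped at 365). Doses are constant per
patient, drawn from `dose_mix`.

Defaults define the reference study conditions: 70% male; age mix
0.5/20/25/14/40.5% over the bands 0–5/6–12/13–18/19–25/>25; diagnoses
recorded 85%; prior MPH 80%; hazards 0.10/0.03 per refill (mean ≈ 6
prescriptions/patient within a 3.3-year window); doses
30/50/70/90 mg/day at 40/35/20/5%; 30-day supplies; 8% late refills;
5% of patients forced to start at 17–18 with an unbroken episode crossing
the adult threshold (exercising the continuation exemption). These are
chosen as plausible for a European ADHD cohort, in the ranges published
drug-utilization work reports — the generator is a test harness, not a
calibration to any country's results.

Crucially, the generator constructs events to respect the 30-day
definitions and returns per-patient ground-truth labels (discontinued,
switched to/from, censored, prior MPH/diagnosis, dose). Event placement
guarantees no accidental window hits: prior-MPH chains sit either inside
or strictly beyond the switch window; post-switch refills cannot fall
within 30 days of any earlier index period end. The classifiers recover
the labels with zero discordance, which is the pipeline's strongest
end-to-end check.

What the generator does **not** emulate: dose titration within a patient,
seasonal prescribing, within-drug overlapping refills (overlap handling
is exercised by dedicated tests instead), informative dropout, regional
or prescriber clustering, and the extreme prescription-count tail of real
multi-year registries. Passing tests therefore show the *analysis logic*
is correct under known event structure, not that real-world estimates
from any particular database would match published figures.

## Aggregation and reporting

Cohort summaries cover index-drug users only. Every percentage is stored
with its evaluable denominator; not-evaluable patients leave a
criterion's denominator. SD uses the sample (n−1) convention, with a
single observation defined as SD 0. Percentages are stored at full
precision and rounded to one decimal only in the formatted view, which
can optionally suppress counts below 6 (a disclosure-control practice of
some EMR providers). The empty cohort yields an explicit all-zero
summary with undefined proportions.

## Problem sizes

Stochastic checks run at n = 5000 patients (binomial tolerances as
documented in each test); the classifier–oracle equivalence covers all
drug/gap patterns up to length 4 over a grid straddling the 30-day
boundary plus 10,000 random sequences up to length 6 with gaps 0–60 days.
The full suite runs in about a minute on one CPU.

## Known limitations

* Average daily dose ignores treatment gaps by design (covered-day
  denominator); with erratic refilling it describes dose-on-supply, not
  consumption.
* Year-granular ages misclassify patients near band edges by up to one
  year; this mirrors registry practice but matters for the age-6 and
  age-19 criteria.
* EMR-style sources record prescriptions written, not filled; the data
  model treats both identically and records the distinction only in the
  source profile description.
* The dose audit trusts recorded instructions; free-text dosing
  instructions must be resolved to mg/day upstream of the schema mapping.
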