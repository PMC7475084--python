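# rxdur

Drug-utilization analysis of longitudinal prescription data: treatment
episodes, persistence, switching, and off-label auditing.

## What this is for

Pharmacoepidemiologists use dispensing/prescription databases (national
registries, EMR panels, pharmacy panels) to describe how a drug is used in
routine care: who receives it, for how long, at what dose, how often
treatment is abandoned or exchanged for another drug, and how much
prescribing falls outside the approved label. `rxdur` implements this
analysis for an index drug — by default lisdexamfetamine (LDX), a
long-acting amphetamine prodrug used second-line in paediatric ADHD after
methylphenidate (MPH) — as a reusable, testable pipeline over plain
delimited text tables of patients, prescriptions and diagnoses.

Because the real sources are access-restricted, the package ships a
synthetic cohort generator that emulates their statistical structure
(country launch dates and observation windows, age/sex mixes, diagnosis
recording completeness, refill behaviour, source-specific missingness) and
records ground-truth event labels, so every stage of the analysis can be
verified end to end without any real data.

## The model

**Coverage.** Each prescription issued at date *t* covers `[t, t + d)`
days, where *d* is the recorded days' supply, else
`quantity × strength / daily instruction`, else a configured default
(30 days). Early refills *stockpile*: their coverage starts when the
previous supply runs out, conserving dispensed days and milligrams.

**Episodes.** Coverage intervals for one patient and drug are merged into
treatment episodes with a grace period *g* = 30 days: an issue at most
*g* days after the running coverage end continues the episode; a longer
gap closes it. Duration of exposure is the sum of episode spans.

**Average daily dose.** ADD = total mg dispensed ÷ total covered days
(treatment gaps excluded). The label cap is 70 mg/day; `ADD > 70` is
flagged, and cohort dose statistics pool only patients at or below the cap.

**Patterns** (all anchored at prescription-period ends, same *g*):

* *discontinuation* — a period ends and no ADHD medication is issued
  within *g* days, with the window fully observed; otherwise the patient
  is censored at the observation end;
* *switch to index* — an index issue within *g* days after the end of
  another ADHD drug's period;
* *switch from index* — any other ADHD drug issued within *g* days after
  the end of an index period.

**Off-label audit.** Declarative per-country rules with effective dates:
no ADHD diagnosis recorded before the first index prescription; no prior
MPH (evaluable only with ≥365 days of history); age < 6 at prescription;
ADD > 70 mg/day; and adult use (age ≥ 19) without an adult approval in
force at the issue date (with an optional age cap, e.g. 55 years in
Switzerland) unless the treatment episode began before adulthood. Flags
are tri-state — true/false/not-evaluable — and missingness propagates from
each source's profile. Eight country configurations are shipped.

## Worked example

`examples/05_full_pipeline.py` simulates 2000 patients under the Swedish
configuration, writes the interchange files, and runs the full pipeline:

```text
cohort summary (selection):
  n_patients                2000.00
  n_prescriptions          11785.00
  male_pct                    70.00
  documented_adhd_pct         85.75
  repeat_users_pct            82.85
  rx_mean                      5.89
  rx_median                    4.50
  exposure_days_mean         244.47
  add_mg_mean                 45.59
  discontinued_pct            67.50
  switched_to_pct             39.30
  switched_from_pct           15.05
  adult_off_label_pct         22.60
  no_prior_mph_pct            18.98
```

Reading: 82.9% of the 2000 index-drug users were repeat users (more than
one prescription); mean exposure was 244 days; the mean average daily dose
among patients within the 70 mg/day cap was 45.6 mg; 67.5% ever met the
30-day discontinuation definition; 39.3% switched to the index drug from
another ADHD medication and 15.1% switched away from it; 22.6% of
age-evaluable patients had adult use outside the label, and 19.0% of
patients with ≥365 days of history had no recorded prior MPH. Other
examples cover episode construction, pattern classification and the
off-label audit one capability at a time.

A thin CLI wraps the two shell-worthy operations:

```bash
rxdur simulate --country sweden --n 1000 --seed 7 --out data/
rxdur run --country sweden --in data/ --out results/ --gap-days 30
rxdur countries
```

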