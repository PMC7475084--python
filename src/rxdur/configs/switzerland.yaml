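country: switzerland
launch_date: 2014-08-01
# adult approval in 2014, limited to adults not older than 55 years
adult_approval_date: 2014-08-01
adult_age_cap: 55
observation_start: 2014-08-01
observation_end: 2017-12-31
min_label_age: 6
adult_age_threshold: 19
max_daily_dose_mg: 70.0
requires_prior_mph: true
requires_recorded_diagnosis: true
mph_lookback_min_enrolment_days: 365
report_adult_off_label: true
sources:
  - source_id: pharmacy_panel
    records_diagnoses: false
    records_ages: true
    records_durations: true
    description: Pharmacy prescription panel (retail dispensings, no diagnoses)
  - source_id: self_dispensing_panel
    records_diagnoses: false
    records_ages: false
    records_durations: false
    description: Self-dispensing physician panel (no diagnoses, ages or durations)
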