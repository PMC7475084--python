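country: united_kingdom
launch_date: 2013-03-01
adult_approval_date: 2015-01-01
adult_age_cap: null
observation_start: 2013-03-01
observation_end: 2017-12-31
min_label_age: 6
adult_age_threshold: 19
max_daily_dose_mg: 70.0
requires_prior_mph: true
requires_recorded_diagnosis: true
mph_lookback_min_enrolment_days: 365
report_adult_off_label: true
sources:
  - source_id: emr
    records_diagnoses: true
    records_ages: true
    records_durations: true
    description: Primary-care EMR research database (prescriptions written)
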