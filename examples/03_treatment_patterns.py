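"""Classify discontinuation and switching on a simulated cohort.

All three definitions share the 30-day grace period: discontinuation is an
index-drug period end with no ADHD prescription in the next 30 days (and
enough follow-up to adjudicate); switches are cross-drug issues inside
that window.
"""

import pandas as pd

from rxdur import (
    SimulationConfig,
    build_coverage,
    classify_patterns,
    load_country_config,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(n_patients=1000, seed=42))
country = load_country_config("sweden")

coverage = build_coverage(cohort.prescriptions)
flags = classify_patterns(
    coverage,
    cohort.prescriptions,
    window_end=pd.Timestamp(country.observation_end),
    gap_days=30,
)

summary = flags[
    ["discontinued", "discontinued_naive", "switched_to_ldx", "switched_from_ldx", "censored"]
].mean()
print("classified pattern rates (fraction of patients):")
print(summary.to_string(float_format="%.3f"))

truth = cohort.truth.set_index("patient_id")
got = flags.set_index("patient_id")
discordant = sum(
    int((got[c].astype(bool) != truth[c].astype(bool)).sum())
    for c in ("discontinued", "switched_to_ldx", "switched_from_ldx", "censored")
)
print(f"\ndiscordance with generated ground truth: {discordant} flags")
print()
print(
    "Zero discordance means the classifiers reproduce every generated event;\n"
    "'naive' discontinuation ignores censoring at the window end and is\n"
    "therefore higher than the adjudicated rate."
)
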