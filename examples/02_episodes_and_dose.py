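"""Build coverage intervals and treatment episodes for one patient.

Three prescriptions: two back-to-back, then a refill after a 45-day gap.
The 30-day grace period merges the first two into one episode and opens a
second episode for the late refill.
"""

import pandas as pd

from rxdur import average_daily_dose, build_coverage, build_episodes, patient_exposure

rx = pd.DataFrame(
    {
        "patient_id": ["P1"] * 3,
        "drug": ["LDX"] * 3,
        "issue_date": pd.to_datetime(["2015-01-01", "2015-01-31", "2015-04-16"]),
        "strength_mg": [50.0, 50.0, 70.0],
        "quantity": [30.0, 30.0, 30.0],
        "daily_dose_instruction_mg": [50.0, 50.0, 70.0],
        "supply_days": pd.array([30, 30, 30], dtype="Int64"),
    }
)

coverage = build_coverage(rx, default_supply_days=30)
print("coverage intervals (one per prescription):")
print(coverage[["start", "end", "days", "dose_mg_per_day", "total_mg"]].to_string(index=False))

episodes = build_episodes(coverage, gap_days=30)
print("\nepisodes (gaps <= 30 days merged):")
print(
    episodes[["episode_id", "start", "end", "n_prescriptions", "covered_days", "span_days"]]
    .to_string(index=False)
)

exposure = patient_exposure(episodes)
add = average_daily_dose(coverage, cap_mg=70.0)
print(f"\nexposure duration: {exposure.loc[0, 'duration_days']} days over "
      f"{exposure.loc[0, 'n_episodes']} episodes")
print(f"average daily dose: {add.loc[0, 'add_mg_per_day']:.1f} mg/day "
      f"(exceeds 70 mg/day cap: {bool(add.loc[0, 'exceeds_cap'])})")
print()
print(
    "Exposure sums episode spans (the 45-day pause is excluded); the dose is\n"
    "total dispensed mg over covered days, so pauses do not dilute it."
)
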