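"""Generate a synthetic drug-utilization cohort and inspect its tables.

The generator emulates a national prescription registry: patients with an
age/sex mix, optional recorded ADHD diagnoses and prior MPH history, then
a refill sequence for the index drug (LDX) with on-time and late gaps,
ending in discontinuation, a switch to another ADHD drug, or the end of
the observation window.
"""

from rxdur import SimulationConfig, simulate_cohort

config = SimulationConfig(n_patients=500, seed=7, country="sweden")
cohort = simulate_cohort(config)

print(f"patients:      {len(cohort.patients)}")
print(f"prescriptions: {len(cohort.prescriptions)}  (all drugs)")
print(f"diagnoses:     {len(cohort.diagnoses)}")
print()
print(cohort.prescriptions.head(8).to_string(index=False))
print()
# the generator records the events it constructed, per patient
rates = cohort.truth[["discontinued", "switched_to_ldx", "switched_from_ldx", "censored"]].mean()
print("generated event rates (fraction of patients):")
print(rates.to_string(float_format="%.3f"))
print()
print(
    "Each rate is the share of patients for whom the generator produced that\n"
    "event under the 30-day grace-period definitions; the classifiers in the\n"
    "patterns module must recover these labels exactly."
)
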