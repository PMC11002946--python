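"""Simulate one virtual adult on the monthly long-acting cabotegravir design.

Four weeks of oral 30 mg/day, a 600 mg intramuscular loading dose at week 4,
then 400 mg injections every 4 weeks: the profile shows the oral lead-in,
the flip-flop release from the depot, and the slow climb to steady state.
"""

from lapbpk import CohortSpec, build_regimen, generate_cohort, load_drug, \
    simulate_profile

individual = generate_cohort(CohortSpec(n=1, age_range=(30.0, 30.0), seed=4,
                                        n_trials=1))[0]
drug = load_drug("cabotegravir")
schedule = build_regimen("cabotegravir", "Q4W")
profile = simulate_profile(individual, drug, schedule)

print(f"individual: {individual.demographics.sex}, "
      f"age {individual.demographics.age:.0f} y, "
      f"BMI {individual.demographics.bmi:.1f}")
for week in (4, 8, 24, 48, 96):
    conc = profile.at(week * 168.0 - 1.0)
    print(f"  predose concentration, week {week:2d}: {conc:7.0f} ng/mL")
print("\nTroughs rise from the first injection toward steady state and stay"
      "\nwell above the 4x protein-adjusted IC90 (664 ng/mL) once established.")
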