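"""Recover a depot release rate by calibrating against trough targets.

Simulates a small cohort with the shipped cabotegravir release rate, takes
the resulting geometric-mean troughs as a zero-width target band, perturbs
the rate by 2x, and lets the calibration utility recover it.
"""

from dataclasses import replace

import numpy as np

from lapbpk import (CohortSpec, TrialConfig, build_regimen, calibrate_depot,
                    generate_cohort, load_drug, run_trial)

drug = load_drug("cabotegravir")
spec = CohortSpec(n=10, age_range=(20.0, 50.0), seed=9, n_trials=10)
cohort = generate_cohort(spec)

truth = run_trial(TrialConfig(
    drug="cabotegravir",
    regimen=build_regimen("cabotegravir", "Q4W", horizon_weeks=16),
    cohort_spec=spec, thresholds=(), sampling_weeks=(8, 16)),
    cohort=cohort, keep_profiles=False)
band = {w: (float(np.exp(np.mean(np.log(truth.troughs[w])))),) * 2
        for w in (8, 16)}

perturbed = replace(drug, depot=replace(drug.depot,
                                        k_release_fast=2 * drug.depot.k_release_fast,
                                        k_release_slow=2 * drug.depot.k_release_slow))
result = calibrate_depot(perturbed, band, cohort, frequency="Q4W",
                         horizon_weeks=16)

print(f"true k_release      : {drug.depot.k_release_fast:.3e} 1/h")
print(f"perturbed start     : {perturbed.depot.k_release_fast:.3e} 1/h")
print(f"recovered k_release : {result.depot.k_release_fast:.3e} 1/h "
      f"({result.n_evaluations} objective evaluations, "
      f"converged={result.converged})")
print("\nRecovery within a few percent shows the trough targets identify the"
      "\nflip-flop release rate.")
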