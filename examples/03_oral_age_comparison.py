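"""Compare oral cabotegravir steady-state exposure in young vs older adults.

Simulates 30 mg once daily to steady state in paired cohorts (n=20 here for
speed; the study design uses n=100) and prints the geometric-mean exposure
metrics and their older/young ratios.
"""

from lapbpk import TrialConfig, build_oral_regimen, fold_change, run_trial
from lapbpk.study import cohort_spec_for

results = {}
for group in ("young", "older"):
    spec = cohort_spec_for(group, seed=123, n=20, n_trials=10)
    config = TrialConfig(drug="cabotegravir",
                         regimen=build_oral_regimen("cabotegravir"),
                         cohort_spec=spec, sampling_weeks=())
    results[group] = run_trial(config, keep_profiles=False).cohort_result

for group, res in results.items():
    g = res.geomean
    print(f"{group:6s}: Cmax {g.cmax:6.0f} ng/mL   "
          f"AUCtau {g.auc_tau:7.0f} ng*h/mL   Cmin {g.cmin:6.0f} ng/mL")

for metric in ("cmax", "auc_tau", "cmin"):
    fc = fold_change(results["older"], results["young"], metric,
                     labels=("older", "young"), seed=0)
    print(f"older/young {metric:7s}: {fc.ratio:.2f} "
          f"(90% band {fc.band[0]:.2f}-{fc.band[1]:.2f})")

print("\nRatios above 1 quantify how much the slower hepatic elimination of"
      "\nolder adults raises exposure; the trough rises most because the"
      "\nhalf-life also lengthens.")
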