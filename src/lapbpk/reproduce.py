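"""End-to-end reproduction of the virtual-trial study endpoints.

Runs the standard study cells (oral steady state and the long-acting Q4W/Q8W
designs, young/middle-aged/older and single-sex cohorts of 100 virtual
adults) and derives the comparison endpoints: older/young and female/male
geometric-mean exposure ratios and the percentage of individuals with
predose concentrations below the efficacy thresholds.

Within a comparison the two cohorts are generated with a *paired* seed
(common random numbers: the same per-individual variability stream, while
ages, sexes and anthropometry follow each cohort's own definition).  The
pairing leaves every cohort marginally identical to an independently seeded
one but sharply reduces the Monte-Carlo error of between-cohort ratios.
"""

from __future__ import annotations

import numpy as np

from .analysis import fold_change, geometric_mean
from .study import cohort_spec_for, derive_seed
from .trial import (DEFAULT_THRESHOLDS, TrialConfig, build_oral_regimen,
                    build_regimen, run_trial)

__all__ = ["StudyEndpoints", "compute_endpoints"]

WEEKS = (8, 44, 48, 96)


class StudyEndpoints:
    """Compute and cache the study's comparison endpoints for one seed."""

    def __init__(self, seed: int, n: int = 100, n_trials: int = 10):
        self.seed = int(seed)
        self.n = int(n)
        self.n_trials = n_trials if n % n_trials == 0 else 1
        self._cells: dict = {}

    def cell(self, drug: str, regimen: str, group: str):
        """One simulated trial cell; the cohort seed is shared across the
        groups of the same (drug, regimen) so comparisons are paired."""
        key = (drug, regimen, group)
        if key not in self._cells:
            seed = derive_seed(self.seed, f"{drug}:{regimen}")
            spec = cohort_spec_for(group, seed=seed, n=self.n,
                                   n_trials=self.n_trials)
            if regimen == "oral":
                config = TrialConfig(drug=drug, regimen=build_oral_regimen(drug),
                                     cohort_spec=spec, sampling_weeks=())
            else:
                config = TrialConfig(drug=drug,
                                     regimen=build_regimen(drug, regimen),
                                     cohort_spec=spec,
                                     thresholds=DEFAULT_THRESHOLDS[drug],
                                     sampling_weeks=WEEKS)
            self._cells[key] = run_trial(config, keep_profiles=False)
        return self._cells[key]

    def ratio(self, drug: str, regimen: str, num: str, den: str,
              metric: str) -> float:
        a = self.cell(drug, regimen, num).cohort_result
        b = self.cell(drug, regimen, den).cohort_result
        return fold_change(a, b, metric, n_boot=0).ratio

    def percent_below(self, drug: str, regimen: str, group: str, week: int,
                      threshold: float) -> float:
        return self.cell(drug, regimen, group).fraction_below(week, threshold)

    def geomean_trough(self, drug: str, regimen: str, group: str,
                       week: int) -> float:
        troughs = self.cell(drug, regimen, group).troughs[week]
        return geometric_mean(troughs)

    def steady_state_relative_change(self, drug: str = "cabotegravir",
                                     regimen: str = "Q4W",
                                     group: str = "young",
                                     weeks=(44, 48)) -> float:
        """Relative trough-to-trough change between two late-study weeks."""
        a = self.geomean_trough(drug, regimen, group, weeks[0])
        b = self.geomean_trough(drug, regimen, group, weeks[1])
        return abs(b - a) / a


def compute_endpoints(seed: int, n: int = 100) -> dict:
    """All headline endpoints of the study, keyed descriptively.

    Ratios are unitless fold changes; ``*_pct_increase`` entries are
    100*(ratio - 1); ``*_pct_below`` entries are percentages of the cohort.
    """
    s = StudyEndpoints(seed, n=n)
    out = {}
    for drug, tag in (("cabotegravir", "cab"), ("rilpivirine", "rpv")):
        for metric in ("cmax", "auc_tau", "cmin"):
            out[f"oral_{tag}_{metric}_older_young"] = s.ratio(
                drug, "oral", "older", "young", metric)
        for regimen in ("Q4W", "Q8W"):
            for metric in ("auc_tau", "cmin"):
                r = s.ratio(drug, regimen, "older", "young", metric)
                out[f"la_{tag}_{regimen.lower()}_{metric}_older_young"] = r
    out["la_cab_q4w_cmin_older_female_male"] = s.ratio(
        "cabotegravir", "Q4W", "older_female", "older_male", "cmin")
    out["la_cab_q4w_auc_older_female_male"] = s.ratio(
        "cabotegravir", "Q4W", "older_female", "older_male", "auc_tau")
    out["cab_q4w_week8_young_pct_below_664"] = s.percent_below(
        "cabotegravir", "Q4W", "young", 8, 664.0)
    out["rpv_q4w_week8_young_pct_below_50"] = s.percent_below(
        "rilpivirine", "Q4W", "young", 8, 50.0)
    out["rpv_q8w_week48_young_pct_below_50"] = s.percent_below(
        "rilpivirine", "Q8W", "young", 48, 50.0)
    out["cab_q4w_young_trough_rel_change_wk44_48"] = \
        s.steady_state_relative_change()
    return out
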