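"""Non-compartmental PK metrics, cohort statistics and comparison tables.

Per individual: Cmax, AUC over a dosing interval (trapezoid on the
simulation grid) and Cmin (the predose value at the interval end).  Per
cohort: geometric means, geometric CV%, 5th-95th percentile bands over time,
and the percentage of individuals with predose concentrations strictly below
an efficacy threshold.  Cohort contrasts are ratios of geometric means with
seeded nonparametric bootstrap 5th-95th bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PKMetrics",
    "CohortResult",
    "FoldChange",
    "compute_pk_metrics",
    "cohort_summary",
    "fold_change",
    "fraction_below",
    "geometric_mean",
    "geometric_cv_percent",
    "build_result_tables",
]

METRIC_NAMES = ("cmax", "auc_tau", "cmin")


@dataclass(frozen=True)
class PKMetrics:
    """Exposure metrics over one dosing interval (ng/mL, ng*h/mL)."""

    cmax: float
    auc_tau: float
    cmin: float
    interval: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cmin > self.cmax + 1e-9:
            raise ValueError(f"cmin {self.cmin} exceeds cmax {self.cmax}")

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclass
class CohortResult:
    """Cohort summary: per-individual metrics plus geometric statistics."""

    per_individual: dict                    # id -> PKMetrics
    geomean: PKMetrics
    cv_percent: dict                        # metric -> geometric CV%
    percentile_band: pd.DataFrame = None    # time_h, p5, p95 (if profiles given)
    threshold_fractions: dict = field(default_factory=dict)  # (week, thr) -> %

    def metric_values(self, metric: str) -> np.ndarray:
        return np.array([m[metric] for m in self.per_individual.values()])


def geometric_mean(values) -> float:
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def geometric_cv_percent(values) -> float:
    """100 * sqrt(exp(var(log x)) - 1), the PK-conventional geometric CV."""
    values = np.asarray(values, dtype=float)
    var = np.var(np.log(values), ddof=1) if len(values) > 1 else 0.0
    return float(100.0 * np.sqrt(np.expm1(var)))


def arithmetic_cv_percent(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(100.0 * np.std(values, ddof=1) / np.mean(values))


def compute_pk_metrics(profile, interval) -> PKMetrics:
    """Cmax / AUCtau / Cmin over ``interval`` (h) of one profile.

    The interval endpoints must lie on the profile grid; Cmin is the value
    at the interval end (the predose sample), AUC is trapezoidal on the
    simulation grid.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    times = profile.times
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9 or t1 <= t0:
        raise ValueError(f"interval {interval} outside profile grid "
                         f"[{times[0]}, {times[-1]}]")
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    tt = times[mask]
    cc = profile.plasma_concentration[mask]
    if abs(tt[0] - t0) > 1e-6 or abs(tt[-1] - t1) > 1e-6:
        raise ValueError("interval endpoints must be on the profile grid")
    return PKMetrics(cmax=float(np.max(cc)),
                     auc_tau=float(np.trapezoid(cc, tt)),
                     cmin=float(cc[-1]),
                     interval=(t0, t1))


def cohort_summary(metrics: Mapping, profiles=None,
                   threshold_fractions: Mapping = None,
                   cv: str = "geometric") -> CohortResult:
    """Summarise per-individual metrics into a :class:`CohortResult`.

    Non-positive metric values (below the concentration floor) are excluded
    from the geometric statistics with a warning count kept implicit in the
    returned per-individual map.  ``cv`` may be "geometric" (default) or
    "arithmetic".
    """
    if len(metrics) < 2:
        raise ValueError("cohort summary requires at least 2 individuals")
    cv_fn = geometric_cv_percent if cv == "geometric" else arithmetic_cv_percent

    geo, cvs = {}, {}
    for name in METRIC_NAMES:
        values = np.array([m[name] for m in metrics.values()])
        positive = values[values > 0]
        if len(positive) < len(values):
            import warnings
            warnings.warn(f"{len(values) - len(positive)} non-positive {name} "
                          "values excluded from cohort statistics")
        geo[name] = geometric_mean(positive)
        cvs[name] = cv_fn(positive)

    band = None
    if profiles:
        times = profiles[0].times
        stack = np.vstack([p.plasma_concentration for p in profiles])
        band = pd.DataFrame({
            "time_h": times,
            "p5": np.percentile(stack, 5, axis=0),
            "p95": np.percentile(stack, 95, axis=0),
            "geomean": np.exp(np.mean(np.log(np.maximum(stack, 1e-12)), axis=0)),
        })

    any_interval = next(iter(metrics.values())).interval
    return CohortResult(
        per_individual=dict(metrics),
        geomean=PKMetrics(cmax=geo["cmax"], auc_tau=geo["auc_tau"],
                          cmin=geo["cmin"], interval=any_interval),
        cv_percent=cvs,
        percentile_band=band,
        threshold_fractions=dict(threshold_fractions or {}))


@dataclass(frozen=True)
class FoldChange:
    """Ratio of cohort geometric means with a bootstrap percentile band."""

    metric: str
    numerator: str
    denominator: str
    ratio: float
    band: tuple = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("fold-change ratio must be positive")


def fold_change(cohort_a: CohortResult, cohort_b: CohortResult, metric: str,
                labels=("a", "b"), n_boot: int = 2000, seed: int = 0) -> FoldChange:
    """Geometric-mean ratio a/b with a seeded bootstrap 5th-95th band."""
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    va = cohort_a.metric_values(metric)
    vb = cohort_b.metric_values(metric)
    ratio = geometric_mean(va) / geometric_mean(vb)
    band = (float("nan"), float("nan"))
    if n_boot:
        rng = np.random.default_rng(seed)
        la, lb = np.log(va), np.log(vb)
        ia = rng.integers(0, len(la), size=(n_boot, len(la)))
        ib = rng.integers(0, len(lb), size=(n_boot, len(lb)))
        boots = np.exp(la[ia].mean(axis=1) - lb[ib].mean(axis=1))
        band = (float(np.percentile(boots, 5)), float(np.percentile(boots, 95)))
    return FoldChange(metric=metric, numerator=labels[0], denominator=labels[1],
                      ratio=float(ratio), band=band)


def fraction_below(troughs: Mapping, week: int, threshold: float) -> float:
    """Percent of individuals with predose concentration strictly below
    ``threshold`` at the sampled ``week`` (ties count as not-below)."""
    if week not in troughs:
        raise KeyError(f"week {week} was not sampled; available: {sorted(troughs)}")
    concs = np.asarray(troughs[week], dtype=float)
    return float(100.0 * np.count_nonzero(concs < threshold) / len(concs))


# ---------------------------------------------------------------------------
# Result tables

def build_result_tables(results: Mapping, fold_seed: int = 0) -> dict:
    """Assemble tidy comparison tables from a grid of trial results.

    ``results`` maps (drug, regimen, group) -> object with a
    ``cohort_result`` attribute (or a bare :class:`CohortResult`), where
    ``regimen`` is "oral", "Q4W" or "Q8W" and ``group`` is an age/sex stratum
    label such as "young", "older", "older_female".  Returns a dict of
    DataFrames: per-cohort summaries, threshold-fraction tables per drug, and
    fold-change tables by age and by sex.  Missing grid cells simply produce
    no rows (explicitly marked absent in the fold tables).
    """
    def res_of(key):
        obj = results[key]
        return getattr(obj, "cohort_result", obj)

    summary_rows = []
    threshold_rows = []
    for (drug, regimen, group), obj in sorted(results.items()):
        cr = getattr(obj, "cohort_result", obj)
        for metric in METRIC_NAMES:
            summary_rows.append({
                "drug": drug, "regimen": regimen, "group": group,
                "metric": metric, "geomean": cr.geomean[metric],
                "cv_percent": cr.cv_percent[metric]})
        for (week, thr), pct in sorted(cr.threshold_fractions.items()):
            threshold_rows.append({
                "drug": drug, "regimen": regimen, "group": group,
                "week": week, "threshold_ng_ml": thr, "percent_below": pct})

    fold_rows = []
    keys = set(results)
    pairs = [
        ("middle", "young"), ("older", "young"),
        ("older_female", "older_male"), ("young_female", "young_male"),
    ]
    drugs = sorted({k[0] for k in keys})
    regimens = sorted({k[1] for k in keys})
    for drug in drugs:
        for regimen in regimens:
            for num, den in pairs:
                ka, kb = (drug, regimen, num), (drug, regimen, den)
                if ka not in keys or kb not in keys:
                    continue
                for metric in ("cmin", "auc_tau", "cmax"):
                    fc = fold_change(res_of(ka), res_of(kb), metric,
                                     labels=(num, den), seed=fold_seed)
                    fold_rows.append({
                        "drug": drug, "regimen": regimen, "metric": metric,
                        "numerator": num, "denominator": den,
                        "ratio": fc.ratio, "p5": fc.band[0], "p95": fc.band[1]})

    tables = {
        "cohort_summary": pd.DataFrame(summary_rows),
        "threshold_fractions": pd.DataFrame(threshold_rows),
        "fold_changes": pd.DataFrame(fold_rows),
    }
    return tables
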