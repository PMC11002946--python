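"""Virtual-population generator with age/sex/anthropometry-dependent physiology.

This module samples cohorts of virtual adults (age, sex, height, weight/BMI)
and derives for each individual the whole-body physiology the PBPK engine
needs: organ volumes, organ blood flows, cardiac output, hematocrit, plasma
binding-protein concentrations, glomerular filtration rate and relative
hepatic enzyme abundances.

All physiological quantities are driven by a versioned coefficients file
(``data/physiology.yaml``): a reference value at age 30 per sex, a piecewise
log-linear age trend, an allometric body-size exponent for volumes, and a
log-normal inter-individual coefficient of variation.  Systemic blood-flow
fractions are renormalised per individual so that the systemic circuit closes
exactly on cardiac output.

Sampling is fully deterministic under a cohort seed: demographics come from
one seeded stream, and every individual carries its own derived integer seed
so physiology is reproducible in isolation.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SEXES",
    "ORGANS",
    "SYSTEMIC_ORGANS",
    "Demographics",
    "PhysiologyState",
    "VirtualIndividual",
    "CohortSpec",
    "load_physiology_coefficients",
    "sample_demographics",
    "derive_physiology",
    "generate_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
    "cohort_to_csv",
    "cohort_from_csv",
    "cohort_to_json",
    "cohort_from_json",
    "reference_muscle_flow",
]

SEXES = ("female", "male")

#: Perfused organ compartments of the whole-body model.
ORGANS = (
    "adipose", "bone", "brain", "gut", "heart", "kidneys", "liver",
    "lungs", "muscle", "pancreas", "skin", "spleen", "rest",
)

#: Organs whose inflow is drawn from arterial blood (terminal systemic
#: branches).  The liver is excluded: it is perfused by the hepatic artery
#: plus the portal outflow of gut, spleen and pancreas.  The lungs sit in
#: series and receive the full cardiac output.
SYSTEMIC_ORGANS = (
    "adipose", "bone", "brain", "gut", "heart", "kidneys", "muscle",
    "pancreas", "skin", "spleen", "rest",
)

SPLANCHNIC_ORGANS = ("gut", "pancreas", "spleen")

AGE_SUPPORT = (20.0, 99.0)

_FLOW_KEYS = SYSTEMIC_ORGANS + ("hepatic_artery",)


class PhysiologyError(ValueError):
    """Raised for demographics or coefficients outside the supported domain."""


@dataclass(frozen=True)
class Demographics:
    """Age (years), sex, body weight (kg) and height (cm) of one individual."""

    age: float
    sex: str
    body_weight: float
    height: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PhysiologyError(f"sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def bmi(self) -> float:
        return self.body_weight / (self.height / 100.0) ** 2


@dataclass
class PhysiologyState:
    """Derived whole-body physiology of one virtual individual.

    Volumes in litres, flows in L/h, albumin and AAG in g/L, GFR in mL/min.
    ``organ_blood_flows`` holds the terminal systemic branches plus
    ``hepatic_artery`` and the composite ``liver`` outflow.
    """

    organ_volumes: dict
    organ_blood_flows: dict
    cardiac_output: float
    hematocrit: float
    albumin: float
    alpha1_acid_glycoprotein: float
    gfr: float
    hepatic_enzyme_abundance: dict

    def systemic_flow_sum(self) -> float:
        return sum(self.organ_blood_flows[k] for k in _FLOW_KEYS)


@dataclass
class VirtualIndividual:
    id: str
    demographics: Demographics
    physiology: PhysiologyState
    rng_seed: int


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one virtual cohort.

    ``n`` individuals with ages uniform on ``age_range``, a deterministic
    female/male split per ``female_fraction``, BMI from a truncated normal on
    ``bmi_range``, partitioned into ``n_trials`` equally sized virtual trials.
    """

    n: int
    age_range: tuple
    female_fraction: float = 0.5
    bmi_range: tuple = (18.5, 30.0)
    seed: int = 0
    n_trials: int = 10

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise PhysiologyError(f"cohort size must be positive, got n={self.n}")
        lo, hi = self.age_range
        if lo > hi:
            raise PhysiologyError(f"age_range min exceeds max: {self.age_range}")
        if lo < AGE_SUPPORT[0] or hi > AGE_SUPPORT[1]:
            raise PhysiologyError(
                f"age_range {self.age_range} outside supported {AGE_SUPPORT}"
            )
        blo, bhi = self.bmi_range
        if blo > bhi:
            raise PhysiologyError(f"bmi_range min exceeds max: {self.bmi_range}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise PhysiologyError(
                f"female_fraction must be in [0, 1], got {self.female_fraction}"
            )
        if self.n_trials <= 0 or self.n % self.n_trials != 0:
            raise PhysiologyError(
                f"n={self.n} must be divisible into n_trials={self.n_trials}"
            )


_COEFF_CACHE: dict = {}


def load_physiology_coefficients(path=None) -> dict:
    """Load (and cache) the physiology coefficients file.

    ``path=None`` loads the packaged defaults.  A light schema check verifies
    the sections and organ keys the engine relies on.
    """
    key = str(path) if path is not None else "__default__"
    if key in _COEFF_CACHE:
        return _COEFF_CACHE[key]
    if path is None:
        ref = importlib.resources.files("lapbpk.data").joinpath("physiology.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    coeffs = yaml.safe_load(text)
    _validate_coefficients(coeffs)
    _COEFF_CACHE[key] = coeffs
    return coeffs


def _validate_coefficients(coeffs: Mapping) -> None:
    for section in ("reference", "demographics", "scalars", "enzymes",
                    "organ_volumes", "flow_fractions", "blood_split"):
        if section not in coeffs:
            raise PhysiologyError(f"physiology coefficients missing section {section!r}")
    vols = coeffs["organ_volumes"]
    for organ in ORGANS:
        if organ not in vols:
            raise PhysiologyError(f"organ_volumes missing organ {organ!r}")
    if "blood" not in vols:
        raise PhysiologyError("organ_volumes missing 'blood'")
    for organ in _FLOW_KEYS:
        if organ not in coeffs["flow_fractions"]:
            raise PhysiologyError(f"flow_fractions missing organ {organ!r}")
    for scalar in ("cardiac_output", "hematocrit", "albumin",
                   "alpha1_acid_glycoprotein", "gfr"):
        if scalar not in coeffs["scalars"]:
            raise PhysiologyError(f"scalars missing {scalar!r}")


def _per_sex(value, sex: str) -> float:
    if isinstance(value, Mapping):
        return float(value[sex])
    return float(value)


def _trend_factor(trend: Mapping, age: float, sex: str, ref_age: float = 30.0) -> float:
    onset = float(trend.get("onset", 50.0))
    s_pre = _per_sex(trend.get("slope_pre", 0.0), sex)
    s_post = _per_sex(trend.get("slope_post", 0.0), sex)
    return float(np.exp(s_pre * (min(age, onset) - ref_age)
                        + s_post * max(age - onset, 0.0)))


def _mean_value(entry: Mapping, age: float, sex: str, ref_age: float) -> float:
    ref = _per_sex(entry["ref"], sex)
    return ref * _trend_factor(entry.get("trend", {}), age, sex, ref_age)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-preserving log-normal perturbation with geometric CV ``cv``."""
    if cv <= 0.0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal() * sigma - 0.5 * sigma * sigma))


def sample_demographics(spec: CohortSpec, coefficients=None) -> list:
    """Sample ``spec.n`` demographic records.

    The female/male split is allocated deterministically (``round(n * f)``
    females), ages are uniform on the cohort range, BMI is a truncated normal
    clipped to the configured bounds, and height is normal per sex with a
    small secular decline in age.  Reproducible bit-for-bit under the seed.
    """
    coeffs = coefficients or load_physiology_coefficients()
    demo = coeffs["demographics"]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))

    n_female = int(round(spec.female_fraction * spec.n))
    sexes = ["female"] * n_female + ["male"] * (spec.n - n_female)

    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n)
    bmis = _truncated_normal(rng, float(demo["bmi_mean"]), float(demo["bmi_sd"]),
                             spec.bmi_range, spec.n)

    records = []
    slope = float(demo.get("height_age_slope_cm_per_year", 0.0))
    for i in range(spec.n):
        sex = sexes[i]
        mean_h = _per_sex(demo["height_mean_cm"], sex) + slope * max(ages[i] - 30.0, 0.0)
        sd_h = _per_sex(demo["height_sd_cm"], sex)
        height = float(np.clip(rng.normal(mean_h, sd_h), mean_h - 3 * sd_h, mean_h + 3 * sd_h))
        weight = bmis[i] * (height / 100.0) ** 2
        records.append(Demographics(age=float(ages[i]), sex=sex,
                                    body_weight=float(weight), height=height))
    return records


def _truncated_normal(rng, mean, sd, bounds, n):
    """Truncated-normal sampling by inverse CDF so every draw respects bounds."""
    from scipy import stats

    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd
    u = rng.uniform(size=n)
    vals = stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    return np.clip(vals, bounds[0], bounds[1])


def derive_physiology(demographics: Demographics, variability_seed: int,
                      coefficients=None, variability: bool = True) -> PhysiologyState:
    """Derive the full physiology of one individual.

    Deterministic given ``(demographics, variability_seed)``.  With
    ``variability=False`` the population-mean physiology for the given
    demographics is returned (two identical individuals then share identical
    physiology).
    """
    coeffs = coefficients or load_physiology_coefficients()
    age, sex = demographics.age, demographics.sex
    if not AGE_SUPPORT[0] <= age <= AGE_SUPPORT[1]:
        raise PhysiologyError(f"age {age} outside supported range {AGE_SUPPORT}")

    ref_age = float(coeffs["reference"]["age"])
    bw_ref = _per_sex(coeffs["reference"]["body_weight_kg"], sex)
    size = demographics.body_weight / bw_ref

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(variability_seed)))

    def draw(entry, allometric=False):
        mean = _mean_value(entry, age, sex, ref_age)
        if allometric:
            b = float(entry.get("allometric_exponent", 1.0))
            mean *= size ** b
        cv = float(entry.get("cv", 0.0)) if variability else 0.0
        return mean * _lognormal_factor(rng, cv)

    scalars = coeffs["scalars"]
    cardiac_output = draw(scalars["cardiac_output"])
    hematocrit = draw(scalars["hematocrit"])
    bounds = scalars["hematocrit"].get("bounds", (0.25, 0.55))
    hematocrit = float(np.clip(hematocrit, bounds[0], bounds[1]))
    albumin = draw(scalars["albumin"])
    aag = draw(scalars["alpha1_acid_glycoprotein"])
    gfr = draw(scalars["gfr"])

    enzymes = {name: draw(entry) for name, entry in coeffs["enzymes"].items()}

    volumes = {}
    for organ in ORGANS:
        volumes[organ] = draw(coeffs["organ_volumes"][organ], allometric=True)
    blood = draw(coeffs["organ_volumes"]["blood"], allometric=True)
    split = coeffs["blood_split"]
    volumes["arterial_blood"] = blood * float(split["arterial"])
    volumes["venous_blood"] = blood * float(split["venous"])

    # Flow fractions: trend + variability, then renormalise so the systemic
    # circuit closes exactly on cardiac output.
    raw = {organ: draw(coeffs["flow_fractions"][organ]) for organ in _FLOW_KEYS}
    total = sum(raw.values())
    flows = {organ: cardiac_output * frac / total for organ, frac in raw.items()}
    flows["liver"] = (flows["hepatic_artery"]
                      + sum(flows[o] for o in SPLANCHNIC_ORGANS))

    return PhysiologyState(
        organ_volumes=volumes,
        organ_blood_flows=flows,
        cardiac_output=cardiac_output,
        hematocrit=hematocrit,
        albumin=albumin,
        alpha1_acid_glycoprotein=aag,
        gfr=gfr,
        hepatic_enzyme_abundance=enzymes,
    )


def _individual_seed(cohort_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(cohort_seed), spawn_key=(1, index))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)


def generate_cohort(spec: CohortSpec, coefficients=None, id_prefix: str = "subj",
                    variability: bool = True) -> list:
    """Generate the full cohort: demographics plus derived physiology.

    Individuals are returned in a stable order; ``n_trials`` consecutive
    blocks of size ``n / n_trials`` form the virtual trials.
    """
    coeffs = coefficients or load_physiology_coefficients()
    demos = sample_demographics(spec, coeffs)
    cohort = []
    for i, demo in enumerate(demos):
        seed_i = _individual_seed(spec.seed, i)
        phys = derive_physiology(demo, seed_i, coeffs, variability=variability)
        cohort.append(VirtualIndividual(
            id=f"{id_prefix}-{i:04d}", demographics=demo, physiology=phys,
            rng_seed=seed_i))
    return cohort


def trial_blocks(spec: CohortSpec, cohort: Sequence) -> list:
    """Partition a cohort into its ``n_trials`` virtual-trial blocks."""
    size = spec.n // spec.n_trials
    return [list(cohort[i * size:(i + 1) * size]) for i in range(spec.n_trials)]


def reference_muscle_flow(coefficients=None, sex: str = "male") -> float:
    """Population reference muscle blood flow (L/h) at age 30, mean size."""
    coeffs = coefficients or load_physiology_coefficients()
    co = _per_sex(coeffs["scalars"]["cardiac_output"]["ref"], sex)
    fracs = {o: _per_sex(coeffs["flow_fractions"][o]["ref"], sex) for o in _FLOW_KEYS}
    total = sum(fracs.values())
    return co * fracs["muscle"] / total


# ---------------------------------------------------------------------------
# Serialization

def _flatten(ind: VirtualIndividual) -> dict:
    d = {
        "id": ind.id,
        "rng_seed": ind.rng_seed,
        "age": ind.demographics.age,
        "sex": ind.demographics.sex,
        "body_weight": ind.demographics.body_weight,
        "height": ind.demographics.height,
        "bmi": ind.demographics.bmi,
        "cardiac_output": ind.physiology.cardiac_output,
        "hematocrit": ind.physiology.hematocrit,
        "albumin": ind.physiology.albumin,
        "alpha1_acid_glycoprotein": ind.physiology.alpha1_acid_glycoprotein,
        "gfr": ind.physiology.gfr,
    }
    for organ, v in ind.physiology.organ_volumes.items():
        d[f"vol_{organ}"] = v
    for organ, q in ind.physiology.organ_blood_flows.items():
        d[f"flow_{organ}"] = q
    for enz, a in ind.physiology.hepatic_enzyme_abundance.items():
        d[f"enz_{enz}"] = a
    return d


def _unflatten(row: Mapping) -> VirtualIndividual:
    demo = Demographics(age=float(row["age"]), sex=str(row["sex"]),
                        body_weight=float(row["body_weight"]),
                        height=float(row["height"]))
    volumes = {k[4:]: float(v) for k, v in row.items() if k.startswith("vol_")}
    flows = {k[5:]: float(v) for k, v in row.items() if k.startswith("flow_")}
    enzymes = {k[4:]: float(v) for k, v in row.items() if k.startswith("enz_")}
    phys = PhysiologyState(
        organ_volumes=volumes, organ_blood_flows=flows,
        cardiac_output=float(row["cardiac_output"]),
        hematocrit=float(row["hematocrit"]), albumin=float(row["albumin"]),
        alpha1_acid_glycoprotein=float(row["alpha1_acid_glycoprotein"]),
        gfr=float(row["gfr"]), hepatic_enzyme_abundance=enzymes)
    return VirtualIndividual(id=str(row["id"]), demographics=demo,
                             physiology=phys, rng_seed=int(row["rng_seed"]))


def cohort_to_frame(cohort: Iterable) -> pd.DataFrame:
    """One row per individual: demographics plus flattened physiology."""
    return pd.DataFrame([_flatten(ind) for ind in cohort])


def cohort_from_frame(frame: pd.DataFrame) -> list:
    return [_unflatten(row) for _, row in frame.iterrows()]


def cohort_to_csv(cohort: Iterable, path) -> None:
    """Write a cohort to CSV such that re-loading is bit-identical."""
    cohort_to_frame(cohort).to_csv(path, index=False)

def cohort_from_csv(path) -> list:
    return cohort_from_frame(pd.read_csv(path, float_precision="round_trip"))


def cohort_to_json(cohort: Iterable) -> str:
    return json.dumps([_flatten(ind) for ind in cohort])


def cohort_from_json(text: str) -> list:
    return [_unflatten(row) for row in json.loads(text)]
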