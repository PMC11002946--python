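"""Drug parameter sets and physiology-based scaling of binding and clearance.

Each compound ships as a versioned YAML file holding physicochemistry
(log P, pKa, unbound fraction, blood:plasma ratio), elimination pathway split
(hepatic enzymes and renal), a reference unbound hepatic intrinsic clearance,
first-order oral absorption and the intramuscular depot parameters.

Per-individual scaling:

* unbound fraction from the binding-protein concentration (albumin or AAG)
  relative to the reference individual;
* blood:plasma ratio from hematocrit, holding the red-cell affinity fixed;
* hepatic clearance by the well-stirred model, with intrinsic clearance
  proportional to liver volume times relative enzyme abundance;
* renal clearance as unbound fraction times GFR;
* depot release rate scaled by muscle perfusion relative to a reference
  (power law), with a small formulation-level log-normal variability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DepotParameterSet",
    "DrugParameterSet",
    "load_drug",
    "individual_fu",
    "individual_blood_to_plasma",
    "hepatic_intrinsic_clearance",
    "scale_clearance",
    "depot_release_rates",
    "BUILTIN_DRUGS",
]

BUILTIN_DRUGS = ("cabotegravir", "rilpivirine")

RENAL = "renal"


class DrugParameterError(ValueError):
    """Raised for inconsistent or unsupported drug parameters."""


@dataclass(frozen=True)
class DepotParameterSet:
    """Intramuscular depot release parameters.

    ``single_first_order`` releases the whole bioavailable dose with
    ``k_release_fast``; ``dual_first_order`` splits it ``fast_fraction`` /
    ``1 - fast_fraction`` between the two rate constants.  ``flow_sensitivity``
    is the exponent of the muscle-perfusion scaling of the release rate.
    """

    release_model: str = "single_first_order"
    k_release_fast: float = 1e-3
    k_release_slow: float = 1e-4
    fast_fraction: float = 1.0
    bioavailable_fraction: float = 1.0
    flow_sensitivity: float = 0.0
    release_cv: float = 0.0
    reference_muscle_flow: float = 66.3

    def __post_init__(self) -> None:
        if self.release_model not in ("single_first_order", "dual_first_order"):
            raise DrugParameterError(
                f"unknown release_model {self.release_model!r}")
        if self.k_release_fast <= 0 or self.k_release_slow <= 0:
            raise DrugParameterError("depot release rates must be positive")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise DrugParameterError("fast_fraction must be in [0, 1]")
        if self.release_model == "single_first_order" and self.fast_fraction != 1.0:
            raise DrugParameterError(
                "single_first_order requires fast_fraction == 1")
        if not 0.0 < self.bioavailable_fraction <= 1.0:
            raise DrugParameterError("bioavailable_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DrugParameterSet:
    name: str
    molecular_weight: float
    log_p: float
    pka_list: tuple
    fu_plasma: float
    blood_to_plasma_ratio: float
    protein_binding_partner: str
    elimination_pathways: Mapping
    intrinsic_clearance_reference: float
    oral_absorption: Mapping
    depot: DepotParameterSet
    kp_scalar: float = 1.0
    reference: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fu_plasma <= 1.0:
            raise DrugParameterError(f"fu_plasma must be in (0, 1], got {self.fu_plasma}")
        total = sum(self.elimination_pathways.values())
        if abs(total - 1.0) > 1e-9:
            raise DrugParameterError(
                f"elimination pathway fractions must sum to 1, got {total}")
        if self.intrinsic_clearance_reference <= 0:
            raise DrugParameterError("intrinsic clearance must be positive")
        if self.protein_binding_partner not in ("albumin", "alpha1_acid_glycoprotein"):
            raise DrugParameterError(
                f"unsupported binding partner {self.protein_binding_partner!r}")
        for key in ("ka", "fa"):
            if key not in self.oral_absorption:
                raise DrugParameterError(f"oral_absorption missing {key!r}")
        if self.oral_absorption["ka"] <= 0:
            raise DrugParameterError("oral ka must be positive")

    @property
    def hepatic_fraction(self) -> float:
        return sum(v for k, v in self.elimination_pathways.items() if k != RENAL)

    @property
    def renal_fraction(self) -> float:
        return float(self.elimination_pathways.get(RENAL, 0.0))


def load_drug(name_or_path, overrides: Mapping = None) -> DrugParameterSet:
    """Load a drug parameter set from a packaged name or a YAML path.

    ``overrides`` (dot-free, top-level or ``depot.*`` keys) allow programmatic
    what-if edits without touching the shipped files.
    """
    if str(name_or_path) in BUILTIN_DRUGS:
        ref = importlib.resources.files("lapbpk.data").joinpath(f"{name_or_path}.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(name_or_path) as fh:
            raw = yaml.safe_load(fh)
    if overrides:
        for key, value in overrides.items():
            if key == "depot" and isinstance(value, Mapping):
                raw["depot"] = {**raw.get("depot", {}), **value}
            else:
                raw[key] = value
    return _from_dict(raw)


def _from_dict(raw: Mapping) -> DrugParameterSet:
    try:
        depot = DepotParameterSet(**raw.get("depot", {}))
        pka = tuple((float(e["value"]), str(e["type"])) for e in raw.get("pka", []))
        return DrugParameterSet(
            name=str(raw["name"]),
            molecular_weight=float(raw["molecular_weight"]),
            log_p=float(raw["log_p"]),
            pka_list=pka,
            fu_plasma=float(raw["fu_plasma"]),
            blood_to_plasma_ratio=float(raw["blood_to_plasma_ratio"]),
            protein_binding_partner=str(raw["protein_binding_partner"]),
            elimination_pathways={str(k): float(v)
                                  for k, v in raw["elimination_pathways"].items()},
            intrinsic_clearance_reference=float(raw["intrinsic_clearance_reference"]),
            oral_absorption={k: float(v) for k, v in raw["oral_absorption"].items()},
            depot=depot,
            kp_scalar=float(raw.get("kp_scalar", 1.0)),
            reference=dict(raw.get("reference", {})),
        )
    except KeyError as exc:
        raise DrugParameterError(f"drug parameter file missing field {exc}") from exc


def _reference(drug: DrugParameterSet, key: str, default: float) -> float:
    return float(drug.reference.get(key, default))


def individual_fu(drug: DrugParameterSet, physiology) -> float:
    """Unbound plasma fraction scaled by the binding-protein concentration.

    1/fu - 1 is proportional to the protein concentration, so
    fu_i = 1 / (1 + (1/fu_ref - 1) * P_i / P_ref).
    """
    if drug.protein_binding_partner == "albumin":
        p_i = physiology.albumin
        p_ref = _reference(drug, "albumin_g_per_l", 46.0)
    else:
        p_i = physiology.alpha1_acid_glycoprotein
        p_ref = _reference(drug, "alpha1_acid_glycoprotein_g_per_l", 0.80)
    bound_ref = 1.0 / drug.fu_plasma - 1.0
    return 1.0 / (1.0 + bound_ref * p_i / p_ref)


def individual_blood_to_plasma(drug: DrugParameterSet, physiology) -> float:
    """Blood:plasma ratio rescaled to the individual's hematocrit."""
    hct_ref = _reference(drug, "hematocrit", 0.45)
    k_rbc = (drug.blood_to_plasma_ratio - (1.0 - hct_ref)) / hct_ref
    return 1.0 - physiology.hematocrit + k_rbc * physiology.hematocrit


def hepatic_intrinsic_clearance(drug: DrugParameterSet, individual) -> float:
    """Unbound intrinsic clearance (L/h) scaled by liver volume and enzymes.

    The reference intrinsic clearance refers to the whole reference liver; it
    scales linearly with the individual liver volume and with the
    abundance-weighted mix of the drug's hepatic elimination pathways.
    """
    phys = individual.physiology
    v_ref = _reference(drug, "liver_volume_l", 1.80)
    hepatic = {k: v for k, v in drug.elimination_pathways.items() if k != RENAL}
    if not hepatic:
        return 0.0
    weight_total = sum(hepatic.values())
    abundance = 0.0
    for enzyme, frac in hepatic.items():
        if enzyme not in phys.hepatic_enzyme_abundance:
            raise DrugParameterError(
                f"pathway enzyme {enzyme!r} absent from physiology state")
        abundance += (frac / weight_total) * phys.hepatic_enzyme_abundance[enzyme]
    return (drug.intrinsic_clearance_reference
            * (phys.organ_volumes["liver"] / v_ref) * abundance)


def scale_clearance(drug: DrugParameterSet, individual) -> dict:
    """Hepatic (well-stirred) and renal plasma clearances (L/h).

    Hepatic: CL_b = Q_h fu_b CLint / (Q_h + fu_b CLint) on blood, converted to
    plasma by the blood:plasma ratio.  Renal: fu * GFR (filtration only).
    """
    phys = individual.physiology
    fu = individual_fu(drug, phys)
    bp = individual_blood_to_plasma(drug, phys)
    clint = hepatic_intrinsic_clearance(drug, individual)
    q_h = phys.organ_blood_flows["liver"]
    fu_b = fu / bp
    cl_h_blood = q_h * fu_b * clint / (q_h + fu_b * clint) if clint > 0 else 0.0
    cl_renal = 0.0
    if drug.renal_fraction > 0:
        cl_renal = fu * phys.gfr * 60.0 / 1000.0   # mL/min -> L/h
    return {"hepatic_cl": cl_h_blood * bp, "renal_cl": cl_renal}


def depot_release_rates(drug: DrugParameterSet, individual) -> tuple:
    """Individual depot release rate constants (fast, slow; 1/h).

    The formulation rates scale with muscle perfusion relative to the
    reference flow raised to ``flow_sensitivity``, times a deterministic
    (seeded per individual) log-normal formulation variability.
    """
    depot = drug.depot
    q_mus = individual.physiology.organ_blood_flows["muscle"]
    scale = (q_mus / depot.reference_muscle_flow) ** depot.flow_sensitivity
    if depot.release_cv > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(individual.rng_seed), spawn_key=(2,)))
        sigma = float(np.sqrt(np.log1p(depot.release_cv ** 2)))
        scale *= float(np.exp(rng.normal() * sigma - 0.5 * sigma * sigma))
    return depot.k_release_fast * scale, depot.k_release_slow * scale
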