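"""Tissue:plasma partition coefficients from tissue composition.

Implements the tissue-composition (Rodgers-Rowland-class) equations used by
perfusion-limited whole-body PBPK models:

* moderate-to-strong bases (any basic pKa >= 7) partition into intracellular
  water by pH trapping and bind electrostatically to acidic phospholipids;
  the phospholipid association constant is back-calculated from red-blood-cell
  partitioning (blood:plasma ratio and hematocrit);
* acids, weak bases, neutrals and zwitterions distribute into tissue water,
  neutral lipids/phospholipids, and bind tissue proteins (albumin for acids
  and weak bases, lipoproteins for neutrals) scaled from the plasma unbound
  fraction.

Adipose uses the vegetable-oil:water partition coefficient
(log P_vow = 1.115 log P - 1.35) in place of octanol:water, as is standard.

The tissue composition table ships as CSV (one row per organ plus plasma and
red blood cells) and can be swapped without code changes.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PartitionCoefficients",
    "load_tissue_composition",
    "compute_partition_coefficients",
    "kp_for_tissues",
]


class PartitionError(ValueError):
    """Raised when a tissue is missing from the composition table."""


@dataclass
class PartitionCoefficients:
    """Map organ -> total tissue:plasma concentration ratio (unitless)."""

    kp: dict

    def __getitem__(self, organ: str) -> float:
        return self.kp[organ]


_COMP_CACHE: dict = {}


def load_tissue_composition(path=None) -> pd.DataFrame:
    key = str(path) if path is not None else "__default__"
    if key in _COMP_CACHE:
        return _COMP_CACHE[key]
    if path is None:
        ref = importlib.resources.files("lapbpk.data").joinpath("tissue_composition.csv")
        text = ref.read_text()
        frame = pd.read_csv(io.StringIO(text), comment="#")
    else:
        frame = pd.read_csv(path, comment="#")
    frame = frame.set_index("tissue")
    _COMP_CACHE[key] = frame
    return frame


def _ionization(pka_list, ph: float) -> float:
    """Solubility ratio Z = [total]/[neutral] at the given pH."""
    z = 1.0
    for entry in pka_list:
        value, kind = _pka_entry(entry)
        if kind == "acid":
            z += 10.0 ** (ph - value)
        elif kind == "base":
            z += 10.0 ** (value - ph)
        else:
            raise PartitionError(f"pKa type must be 'acid' or 'base', got {kind!r}")
    return z


def _pka_entry(entry):
    if isinstance(entry, Mapping):
        return float(entry["value"]), str(entry["type"])
    value, kind = entry
    return float(value), str(kind)


def _is_moderate_strong_base(pka_list) -> bool:
    return any(kind == "base" and value >= 7.0
               for value, kind in map(_pka_entry, pka_list))


def _lipid_term(p: float, f_nl: float, f_np: float) -> float:
    return p * f_nl + (0.3 * p + 0.7) * f_np


def _partition_p(log_p: float, adipose: bool) -> float:
    if adipose:
        return 10.0 ** (1.115 * log_p - 1.35)
    return 10.0 ** log_p


def kp_for_tissues(log_p: float, pka_list, fu: float, blood_to_plasma: float,
                   hematocrit: float, composition: pd.DataFrame,
                   tissues=None, kp_scalar: float = 1.0) -> dict:
    """Compute Kp (total tissue:plasma) for the requested tissues.

    ``composition`` must contain rows for each tissue plus ``plasma`` and
    ``red_blood_cells``.
    """
    if not 0.0 < fu <= 1.0:
        raise PartitionError(f"fu must be in (0, 1], got {fu}")
    plasma = composition.loc["plasma"]
    ph_p = float(plasma["ph"])
    z_p = _ionization(pka_list, ph_p)
    strong_base = _is_moderate_strong_base(pka_list)

    ka_ap = 0.0
    if strong_base:
        rbc = composition.loc["red_blood_cells"]
        z_bc = _ionization(pka_list, float(rbc["ph"]))
        kpu_bc = (blood_to_plasma - (1.0 - hematocrit)) / (hematocrit * fu)
        p = _partition_p(log_p, adipose=False)
        resid = (kpu_bc
                 - (z_bc / z_p) * float(rbc["f_iw"])
                 - _lipid_term(p, float(rbc["f_nl"]), float(rbc["f_np"])) / z_p)
        ap_bc = float(rbc["ap_mg_per_g"])
        ka_ap = max(resid, 0.0) * z_p / ((z_bc - 1.0) * ap_bc)

    if tissues is None:
        tissues = [t for t in composition.index
                   if t not in ("plasma", "red_blood_cells")]

    kps = {}
    for tissue in tissues:
        if tissue not in composition.index:
            raise PartitionError(f"no tissue composition available for organ {tissue!r}")
        row = composition.loc[tissue]
        p = _partition_p(log_p, adipose=(tissue == "adipose"))
        z_t = _ionization(pka_list, float(row["ph"]))
        water = float(row["f_ew"]) + (z_t / z_p) * float(row["f_iw"])
        lipid = _lipid_term(p, float(row["f_nl"]), float(row["f_np"])) / z_p
        if strong_base:
            protein = ka_ap * float(row["ap_mg_per_g"]) * (z_t - 1.0) / z_p
            kpu = water + lipid + protein
        else:
            is_neutral = not any(True for _ in pka_list)
            ratio_col = "lipoprotein_ratio" if is_neutral else "albumin_ratio"
            plasma_lipid = _lipid_term(p, float(plasma["f_nl"]),
                                       float(plasma["f_np"])) / z_p
            protein = (1.0 / fu - 1.0 - plasma_lipid) * float(row[ratio_col])
            kpu = water + lipid + protein
        kp = max(kpu, 1e-6) * fu * kp_scalar
        kps[tissue] = float(kp)
    return kps


def compute_partition_coefficients(drug, individual,
                                   composition: pd.DataFrame = None,
                                   tissues=None) -> PartitionCoefficients:
    """Partition coefficients for one drug in one virtual individual.

    Pure function of the drug's physicochemistry and the individual's
    hematocrit (through blood-cell partitioning) and plasma binding-protein
    level (through the unbound fraction).
    """
    from .drugs import individual_fu, individual_blood_to_plasma
    from .population import ORGANS

    comp = composition if composition is not None else load_tissue_composition()
    fu = individual_fu(drug, individual.physiology)
    bp = individual_blood_to_plasma(drug, individual.physiology)
    kps = kp_for_tissues(drug.log_p, drug.pka_list, fu, bp,
                         individual.physiology.hematocrit, comp,
                         tissues=tissues or list(ORGANS),
                         kp_scalar=drug.kp_scalar)
    return PartitionCoefficients(kp=kps)
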