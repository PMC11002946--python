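"""Study-level orchestration: configuration, seeds, outputs, manifest.

A study is a grid of (drug, regimen, cohort) cells.  One master seed
deterministically derives an independent seed per cohort label (splittable
scheme keyed on a stable hash of the label), so adding a cohort to a config
never perturbs the cohorts already defined.  Outputs are tidy CSV tables and
a JSON manifest listing every emitted file with its SHA-256 checksum and the
hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .population import CohortSpec, cohort_to_frame, generate_cohort
from .trial import (DEFAULT_THRESHOLDS, TrialConfig, build_oral_regimen,
                    build_regimen, run_trial)

__all__ = ["RunConfig", "run_study", "derive_seed", "AGE_GROUPS"]

log = logging.getLogger("lapbpk")

#: Age ranges (years) of the standard cohorts.
AGE_GROUPS = {
    "young": (20.0, 50.0),
    "middle": (50.0, 65.0),
    "older": (65.0, 85.0),
}


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic, label-keyed sub-seed below 2**31."""
    key = zlib.crc32(label.encode())
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)


def cohort_spec_for(group: str, seed: int, n: int = 100,
                    female_fraction: float = None, n_trials: int = 10) -> CohortSpec:
    """Standard cohort spec for an age group (optionally single-sex).

    ``group`` may carry a ``_female`` / ``_male`` suffix for the sex-effect
    cohorts (e.g. ``older_female``).
    """
    base = group
    ff = female_fraction
    for suffix, frac in (("_female", 1.0), ("_male", 0.0)):
        if group.endswith(suffix):
            base = group[: -len(suffix)]
            ff = frac if ff is None else ff
    if base not in AGE_GROUPS:
        raise ValueError(f"unknown age group {base!r}; known: {sorted(AGE_GROUPS)}")
    return CohortSpec(n=n, age_range=AGE_GROUPS[base],
                      female_fraction=0.5 if ff is None else ff,
                      seed=seed, n_trials=n_trials)


@dataclass(frozen=True)
class RunConfig:
    """Declarative study configuration.

    ``cells`` is a list of (drug, regimen, group) labels; regimen is "oral",
    "Q4W" or "Q8W".  All randomness derives from ``seed``; there is no
    wall-clock seeding anywhere.
    """

    cells: tuple
    n: int = 100
    n_trials: int = 10
    seed: int = 20240301
    sampling_weeks: tuple = (8, 48, 96)
    horizon_weeks: int = 96
    export_profiles: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cells = tuple(tuple(c) for c in raw["cells"])
        for cell in cells:
            if len(cell) != 3:
                raise ValueError(f"cell must be (drug, regimen, group): {cell}")
        kwargs = {k: raw[k] for k in
                  ("n", "n_trials", "seed", "horizon_weeks", "export_profiles")
                  if k in raw}
        if "sampling_weeks" in raw:
            kwargs["sampling_weeks"] = tuple(raw["sampling_weeks"])
        return cls(cells=cells, **kwargs)

    def config_hash(self) -> str:
        payload = json.dumps({
            "cells": self.cells, "n": self.n, "n_trials": self.n_trials,
            "seed": self.seed, "sampling_weeks": self.sampling_weeks,
            "horizon_weeks": self.horizon_weeks}, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config: RunConfig, outdir) -> dict:
    """Execute every study cell and write tables plus a manifest.

    Returns the manifest dict.  A failing cell aborts with the completed
    cells recorded in the manifest (written before the exception is
    re-raised) so partial progress is inspectable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "cells": [], "files": {}}
    results = {}

    def emit(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest["files"][name] = _sha256(path)

    try:
        for drug, regimen, group in config.cells:
            label = f"{drug}:{regimen}:{group}"
            seed = derive_seed(config.seed, label)
            spec = cohort_spec_for(group, seed=seed, n=config.n,
                                   n_trials=config.n_trials)
            if regimen == "oral":
                schedule = build_oral_regimen(drug)
                tc = TrialConfig(drug=drug, regimen=schedule, cohort_spec=spec,
                                 sampling_weeks=())
            else:
                schedule = build_regimen(drug, regimen,
                                         horizon_weeks=config.horizon_weeks)
                tc = TrialConfig(drug=drug, regimen=schedule, cohort_spec=spec,
                                 thresholds=DEFAULT_THRESHOLDS[drug],
                                 sampling_weeks=config.sampling_weeks)
            log.info("running cell %s (seed %d)", label, seed)
            res = run_trial(tc, keep_profiles=config.export_profiles)
            results[(drug, regimen, group)] = res
            manifest["cells"].append({"cell": label, "seed": seed, "n": config.n})

            cohort_frame = cohort_to_frame(res.cohort)
            emit(f"cohort_{drug}_{regimen}_{group}.csv", cohort_frame)
            if config.export_profiles and res.profiles:
                rows = []
                for p in res.profiles:
                    rows.append(pd.DataFrame({
                        "individual_id": p.individual_id, "drug": p.drug,
                        "regimen": p.regimen_id, "time_week": p.times_weeks,
                        "conc_ng_per_ml": p.plasma_concentration}))
                emit(f"profiles_{drug}_{regimen}_{group}.csv",
                     pd.concat(rows, ignore_index=True))
    except Exception:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    tables = analysis.build_result_tables(results, fold_seed=config.seed)
    for name, frame in tables.items():
        emit(f"{name}.csv", frame)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
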