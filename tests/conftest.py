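import numpy as np
import pytest

from lapbpk import (CohortSpec, Demographics, derive_physiology, generate_cohort,
                    load_drug)
from lapbpk.population import VirtualIndividual


@pytest.fixture(scope="session")
def cab():
    return load_drug("cabotegravir")


@pytest.fixture(scope="session")
def rpv():
    return load_drug("rilpivirine")


def make_individual(age=35.0, sex="male", bmi=25.0, height=None, seed=123,
                    variability=False, ident="ref"):
    """One individual with population-mean (or seeded) physiology."""
    if height is None:
        height = 176.0 if sex == "male" else 163.0
    demo = Demographics(age=age, sex=sex, body_weight=bmi * (height / 100.0) ** 2,
                        height=height)
    phys = derive_physiology(demo, seed, variability=variability)
    return VirtualIndividual(id=ident, demographics=demo, physiology=phys,
                             rng_seed=seed)


@pytest.fixture(scope="session")
def reference_individual():
    return make_individual()


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n=10, age_range=(20.0, 50.0), seed=42, n_trials=2)
    return spec, generate_cohort(spec)
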