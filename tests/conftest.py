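import copy

import numpy as np
import pytest
from hypothesis import settings

import asthma_cea as ac

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def life_table():
    return ac.default_life_table()


@pytest.fixture()
def params():
    return ac.default_parameter_set()


@pytest.fixture(scope="session")
def base_result(life_table):
    """Deterministic 50-year base case on the bundled fixture inputs."""
    return ac.evaluate(ac.default_parameter_set(), ac.RunConfig(), life_table)


@pytest.fixture(scope="session")
def base_psa(life_table):
    """One shared 1000-iteration PSA run (seeded)."""
    return ac.run_psa(ac.default_parameter_set(), ac.RunConfig(), life_table,
                      n=1000, seed=20190)


def make_flat_life_table(q_female: float, q_male: float,
                         max_age: int = 110) -> ac.LifeTable:
    """A life table with age-constant annual death probabilities."""
    ages = np.arange(max_age + 1)
    qf = np.full(ages.shape, q_female, dtype=float)
    qm = np.full(ages.shape, q_male, dtype=float)
    qf[-1] = qm[-1] = 1.0
    return ac.LifeTable(ages, qf, qm)


@pytest.fixture(scope="session")
def zero_mortality_table():
    return make_flat_life_table(0.0, 0.0)


def equal_arms_params() -> ac.ParameterSet:
    """Fixture inputs with the comparator made identical to the intervention."""
    p = ac.default_parameter_set()
    clone = copy.deepcopy(p.intervention)
    clone.name = p.comparator.name
    p.comparator = clone
    p.distribution_specs = []
    p.dsa_ranges = {}
    return p
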