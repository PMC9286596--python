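"""Shared fixtures: one simulated scenario reused across the suite."""

import numpy as np
import pytest

from peatfire import GridSpec, SyntheticScenario, simulate_scenario
from peatfire import pipeline as P


@pytest.fixture(scope="session")
def grid():
    return GridSpec(origin_x=0.0, origin_y=15000.0, cell_size=250.0,
                    n_rows=60, n_cols=60)


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def result(scenario, grid):
    return simulate_scenario(scenario, grid)


@pytest.fixture(scope="session")
def stacks_and_params(result):
    return P.build_feature_stacks(result)


@pytest.fixture(scope="session")
def stacks(stacks_and_params):
    return stacks_and_params[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
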