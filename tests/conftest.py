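import numpy as np
import pandas as pd
import pytest

from twinlat.scoring import ITEMS, ItemResponse
from twinlat.simulate import SimulationConfig, simulate_cohort, simulate_pairs


def all_right_record(degree="always"):
    return {i: ItemResponse(i, "right", degree) for i in ITEMS}


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort (30 MZ + 40 DZ pairs, 80 singletons)."""
    config = SimulationConfig(n_mz=30, n_dz=40, n_singletons=80)
    return simulate_cohort(config, seed=11)


@pytest.fixture(scope="session")
def continuous_pairs():
    """2,000 + 2,000 simulated twin pairs for one continuous trait."""
    config = SimulationConfig(a2=(0.25, 0.2), c2=(0.10, 0.0))
    df = simulate_pairs(config, rng=np.random.default_rng(99), n_mz=2000, n_dz=2000)
    return df.rename(columns={"liab1_t1": "y_t1", "liab1_t2": "y_t2"})


@pytest.fixture(scope="session")
def bivariate_pairs():
    """Study-scale bivariate pairs under the default generating model."""
    config = SimulationConfig()
    df = simulate_pairs(config, rng=np.random.default_rng(7), n_mz=91, n_dz=114)
    return df.rename(
        columns={
            "liab1_t1": "y1_t1",
            "liab1_t2": "y1_t2",
            "liab2_t1": "y2_t1",
            "liab2_t2": "y2_t2",
        }
    )
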