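import numpy as np
import pandas as pd
import pytest

from methregen.io import BetaMatrix
from methregen.simulate import ClockSimConfig, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One-arm synthetic study at desk-test scale, shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=300,
        n_animals={"YV": 0, "OV": 10, "OS": 0},
        clock=ClockSimConfig(n_clock_cpgs=20),
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def full_study():
    """Three-arm study with default effect structure (smaller gene count)."""
    cfg = SimulationConfig(seed=7, n_genes=400)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_beta():
    """Deterministic 4-probe x 4-sample beta matrix."""
    values = pd.DataFrame(
        {
            "s1": [0.1, 0.5, 0.9, 0.3],
            "s2": [0.2, 0.4, 0.8, 0.3],
            "s3": [0.3, 0.6, 0.7, 0.3],
            "s4": [0.4, 0.5, 0.6, 0.3],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return BetaMatrix(values)
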