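import sys
from pathlib import Path

import numpy as np
import pytest

import pcbscan as pk

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture(scope="session")
def small_cohort():
    """120 subjects, 50 future cases, 8 batches — shared read-only fixture."""
    return pk.generate_cohort(
        120, 50, config=pk.CohortConfig(n_batches=8), seed=11
    )


@pytest.fixture(scope="session")
def null_expression(small_cohort):
    truth = pk.SimulationTruth.null(150, sigma2_u=0.2)
    return pk.generate_expression(small_cohort, truth, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
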