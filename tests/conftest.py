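import numpy as np
import pytest

from xnapore import (ExtendedSequence, SimulationConfig, StepSequence,
                     generate_synthetic_table, ideal_level_series)
from xnapore.scenarios import CONTEXT_30


@pytest.fixture(scope="session")
def table4():
    """Default 6^4 table, seed 0."""
    return generate_synthetic_table(seed=0)


@pytest.fixture(scope="session")
def context_seq():
    return ExtendedSequence("ctx", CONTEXT_30)


@pytest.fixture(scope="session")
def steps_phi29(context_seq, table4):
    return ideal_level_series(context_seq, table4, "phi29")


@pytest.fixture(scope="session")
def steps_hel308(context_seq, table4):
    return ideal_level_series(context_seq, table4, "hel308")


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=0)


def make_steps(currents, enzyme_mode="phi29", k=4):
    """Bare StepSequence from explicit currents (for synthetic tests)."""
    n = len(currents)
    return StepSequence(
        np.asarray(currents, float), ("full",) * n,
        tuple((i, i + k - 1) for i in range(1, n + 1)), enzyme_mode, k, "synthetic",
    )
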