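import numpy as np
import pytest

from ecindex.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort: 3 planted miRNAs among 40 probes."""
    cfg = SimulationConfig(
        n_case=25, n_control=25, n_mirna=40, n_differential=3,
        effect_size=2.5, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
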