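import numpy as np
import pandas as pd
import pytest

from clonescreen import ChipSpec, ExperimentDesign, simulate_chip

#: single fixed seed used across the stochastic test suite
SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def baseline_design():
    return ExperimentDesign(effect_sdu=1.0, replicates=8)


@pytest.fixture
def clone_design():
    return ExperimentDesign(effect_sdu=1.0, replicates=8, sigma_clone=0.2)


@pytest.fixture
def chip():
    """A simulated 48x48 chip with the default fresh/frozen shift."""
    return simulate_chip(ChipSpec(), seed=SEED)


@pytest.fixture
def random_expression(rng):
    """A small all-expressed expression matrix for filter identity tests."""
    values = pd.DataFrame(
        rng.uniform(1.0, 20.0, size=(12, 10)),
        index=[f"S{i}" for i in range(12)],
        columns=[f"P{j}" for j in range(10)],
    )
    return values
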