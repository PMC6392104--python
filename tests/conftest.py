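import numpy as np
import pytest

from cd8sim import (
    MolecularParams,
    run_primary,
    run_secondary,
    scaled_preset,
)


@pytest.fixture(scope="session")
def default_params():
    return MolecularParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def primary_run():
    """One scaled-down primary response shared across tests."""
    return run_primary(scaled_preset(seed=1))


@pytest.fixture(scope="session")
def primary_run_2():
    return run_primary(scaled_preset(seed=2))


@pytest.fixture(scope="session")
def secondary_run():
    return run_secondary(scaled_preset(seed=1))


@pytest.fixture(scope="session")
def secondary_run_2():
    return run_secondary(scaled_preset(seed=2))
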