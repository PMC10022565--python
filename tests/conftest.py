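import numpy as np
import pytest

from mhsim import (
    PopulationSpec,
    default_parameter_set,
    gen_population,
    run_scenarios,
)


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic parameter bundle (calibrated to the published
    aggregates)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def small_population():
    return gen_population(PopulationSpec(n=2_000, seed=7))


@pytest.fixture(scope="session")
def clone_run_100k(bundle):
    """A 100,000-individual run with the intervention table equal to the
    base table (shared by the clone-null and self-validation checks)."""
    pop = gen_population(PopulationSpec(n=100_000, seed=11))
    return run_scenarios(pop, bundle.cif, bundle.cif, bundle.gompertz)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
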