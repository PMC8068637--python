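import pytest

from shiftsem.estimation import compute_moments
from shiftsem.model_core import (
    apply_identification,
    build_parameter_table,
)
from shiftsem.procedure import step1_establish_lmm, step2_omnibus
from shiftsem.simulate import (
    SimulationSpec,
    example_generating_table,
    example_pattern,
    generate_dataset,
)


@pytest.fixture(scope="session")
def pattern():
    return example_pattern()


@pytest.fixture(scope="session")
def generating_table():
    return example_generating_table()


@pytest.fixture(scope="session")
def null_data(generating_table):
    """One dataset simulated from the canonical model without any shift."""
    return generate_dataset(SimulationSpec(table=generating_table, n=500, seed=20260927))


@pytest.fixture(scope="session")
def null_moments(null_data, pattern):
    return compute_moments(null_data, pattern.column_names())


@pytest.fixture(scope="session")
def step1_table(pattern):
    return apply_identification(build_parameter_table(pattern), "step1")


@pytest.fixture(scope="session")
def step1_fitted(null_moments, pattern):
    return step1_establish_lmm(null_moments, pattern)


@pytest.fixture(scope="session")
def step2_result(step1_fitted):
    return step2_omnibus(step1_fitted)
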