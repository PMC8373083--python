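import numpy as np
import pytest

from poolcs import (
    MeasurementMatrix,
    SyntheticProfileSpec,
    generate_measurement_matrix,
    simulate_scep,
)


@pytest.fixture(scope="session")
def small_scep():
    """64-cell, 300-gene high-sparsity profile shared by fast tests."""
    return simulate_scep(
        SyntheticProfileSpec(n_cells=64, n_genes=300, seed=101)
    )


@pytest.fixture(scope="session")
def small_design():
    return generate_measurement_matrix(35, 64, 0.5, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_design(rng, n_pools, n_cells, prob=0.5):
    """Direct Bernoulli draw for property tests (may contain empty rows)."""
    values = (rng.random((n_pools, n_cells)) < prob).astype(float)
    # patch empty rows/cols so the matrix is a valid design
    for i in np.flatnonzero(values.sum(axis=1) == 0):
        values[i, rng.integers(n_cells)] = 1.0
    for j in np.flatnonzero(values.sum(axis=0) == 0):
        values[rng.integers(n_pools), j] = 1.0
    return MeasurementMatrix(values=values)
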