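import numpy as np
import pytest

from regplsc.model_spec import (
    DesignCell,
    build_population,
    coefficients_for_cell,
    load_coefficient_table,
    simulation_model_spec,
)


@pytest.fixture(scope="session")
def table():
    return load_coefficient_table()


@pytest.fixture(scope="session")
def sim_spec():
    """Six-latent-variable study model at moderate collinearity."""
    return simulation_model_spec(phi=0.4)


@pytest.fixture(scope="session")
def cell_high_rel():
    """Reference design cell: N=30, phi=0.4, reliability 0.8, R^2=0.25."""
    return DesignCell(N=30, phi=0.4, reliability=0.8, r2=0.25)


@pytest.fixture(scope="session")
def pop_high_rel(cell_high_rel):
    return build_population(cell_high_rel)


@pytest.fixture(scope="session")
def truth_high_rel(cell_high_rel):
    return coefficients_for_cell(cell_high_rel)


@pytest.fixture(scope="session")
def sample_medium(pop_high_rel):
    """A fixed N=500 draw from the reference population."""
    rng = np.random.default_rng(20240901)
    L = np.linalg.cholesky(pop_high_rel.Sigma)
    X = rng.standard_normal((500, 24)) @ L.T
    import pandas as pd

    return pd.DataFrame(X, columns=list(pop_high_rel.spec.indicators))
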