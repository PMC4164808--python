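import numpy as np
import pytest
from hypothesis import settings

import fermopt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def factors():
    return fermopt.default_factors()


@pytest.fixture(scope="session")
def table2():
    return fermopt.table2_fixture()


@pytest.fixture(scope="session")
def fitted_fixture_model(table2):
    """One 6-10-1 model trained on the packaged fixture, shared across tests."""
    model, result, _ = fermopt.fit_surrogate(
        table2,
        n_hidden=10,
        training=fermopt.TrainingConfig(max_epochs=1000, n_restarts=10, seed=1),
    )
    return model, result


@pytest.fixture
def toy_model(factors):
    """A small hand-built surrogate with identity-friendly scalers."""
    rng = np.random.default_rng(42)
    topo = fermopt.NetworkTopology(n_in=6, n_hidden=4)
    params = fermopt.NetworkParams(
        hidden_weights=rng.normal(size=(4, 6)) * 0.3,
        input_bias=rng.normal(size=4) * 0.1,
        output_weights=rng.normal(size=4),
        output_bias=0.2,
    )
    lows = np.array([f.low for f in factors])
    highs = np.array([f.high for f in factors])
    x_scaler = fermopt.ScalerParams(lows, highs)
    y_scaler = fermopt.ScalerParams(np.array([0.0]), np.array([10.0]))
    return fermopt.SurrogateModel(topo, params, x_scaler, y_scaler)
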