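import numpy as np
import pytest

from missarf.dataset import Dataset
from missarf.forest import ARFConfig, train_arf
from missarf.leaves import fit_density_model

from helpers import continuous_schema, make_two_cluster_data


@pytest.fixture(scope="session")
def two_cluster_model():
    """An ARF density model trained on the two-cluster toy."""
    data = make_two_cluster_data(seed=0)
    forest, _ = train_arf(data, ARFConfig(seed=11))
    return data, fit_density_model(forest, data)


@pytest.fixture(scope="session")
def bivariate_normal_model():
    """Density model trained on a correlated bivariate normal (rho = 0.5)."""
    rng = np.random.default_rng(42)
    cov = np.array([[1.0, 0.5], [0.5, 1.0]])
    X = rng.multivariate_normal([0.0, 0.0], cov, size=1500)
    data = Dataset(X, continuous_schema(2))
    forest, _ = train_arf(data, ARFConfig(seed=7))
    return data, fit_density_model(forest, data)
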