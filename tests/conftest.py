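import numpy as np
import pytest

from ttemeta.inference import PopulationModel
from ttemeta.synthetic import make_benchmark_suite


@pytest.fixture(scope="session")
def bundle():
    """Deterministic synthetic benchmark bundle shared across tests."""
    return make_benchmark_suite(seed=12345)


@pytest.fixture(scope="session")
def recovery_truth():
    return PopulationModel("weibull", 40.0, 2.2, {}, 0.3, 0.3, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
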