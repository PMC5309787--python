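import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oncoresponse.matrix import ExpressionMatrix
from oncoresponse.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded 14-vs-34 cohort with ten planted genes (shared across tests)."""
    config = SyntheticConfig(seed=3)
    matrix, response, mutations, truth = generate_cohort(config)
    return config, matrix, response, mutations, truth


@pytest.fixture
def tiny_matrix():
    """Hand-sized 4-gene x 6-sample matrix for arithmetic checks."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(0.0, 50.0, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(values)
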