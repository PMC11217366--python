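import numpy as np
import pandas as pd
import pytest

from bcsubtype import ExpressionMatrix, make_centroids
from bcsubtype.simulate import SimulationConfig, make_trial_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def centroids5():
    """Five correlated subtype prototypes over 50 genes."""
    return make_centroids(n_genes=50, seed=1)


@pytest.fixture
def random_matrix(rng):
    genes = [f"g{i:03d}" for i in range(20)]
    samples = [f"s{j:02d}" for j in range(10)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 2, (20, 10)), index=genes, columns=samples)
    )


@pytest.fixture
def count_matrix(rng):
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j:02d}" for j in range(8)]
    return ExpressionMatrix(
        pd.DataFrame(
            rng.poisson(200, (50, 8)).astype(float), index=genes, columns=samples
        ),
        "counts",
    )


@pytest.fixture(scope="session")
def scenario():
    """One full biased-trial scenario shared across read-only tests."""
    return make_trial_scenario(SimulationConfig(seed=3))
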