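import numpy as np
import pandas as pd
import pytest

from ohnolog import ExpressionMatrix, SimulationConfig, simulate_dataset


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Three genes x three libraries with hand-checkable proportions."""
    counts = pd.DataFrame(
        {
            "brain": [39, 0, 0],
            "liver": [0, 39, 0],
            "egg": [0, 39, 0],
        },
        index=["single", "double", "silent"],
    )
    sizes = pd.Series({"brain": 3900, "liver": 3900, "egg": 3900})
    return ExpressionMatrix(counts=counts, library_sizes=sizes)


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=400,
        n_libraries=6,
        library_sizes=[4000, 5000, 6000, 8000, 10000, 12000],
        seed=7,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One mid-sized draw under the default (study-scale) conditions."""
    return simulate_dataset(SimulationConfig(n_genes=2000, seed=11))


def random_features(n=300, p=4, seed=0, missing_rate=0.0, beta=None):
    """Small random feature table + logistic outcomes for model tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = rng.normal(scale=0.5, size=p)
    eta = X @ beta
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    cols = [f"v{j}" for j in range(p)]
    df = pd.DataFrame(X, columns=cols)
    if missing_rate > 0:
        mask = rng.random((n, p)) < missing_rate
        df = df.mask(pd.DataFrame(mask, columns=cols))
    df.insert(0, "outcome", y)
    df.index = [f"g{i}" for i in range(n)]
    return df, np.asarray(beta)
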