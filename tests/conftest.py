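import numpy as np
import pandas as pd
import pytest

from pbmcscore import ScoreDefinition, SimulationConfig, generate_dataset

REDUCED_ITEMS = (
    "having_money",
    "distance_to_facility",
    "finding_transport",
    "going_alone",
)


@pytest.fixture(scope="session")
def calibrated_dataset():
    """One draw from the default calibrated simulator (n = 1787)."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def reduced_definition():
    return ScoreDefinition(items=REDUCED_ITEMS)


def exchangeable_items(k: int, r: float, n: int, seed: int = 0) -> pd.DataFrame:
    """Continuous items whose SAMPLE correlation matrix is exactly exchangeable.

    Draws Gaussian data, whitens it against its own sample covariance, then
    colors with the Cholesky factor of the target matrix — so closed-form
    identities (Spearman-Brown, KMO for equicorrelated items) hold exactly.
    """
    rng = np.random.default_rng(seed)
    target = np.full((k, k), r)
    np.fill_diagonal(target, 1.0)
    z = rng.normal(size=(n, k))
    z = z - z.mean(axis=0)
    cov = np.cov(z, rowvar=False, ddof=1)
    white = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    x = white @ np.linalg.cholesky(target).T
    return pd.DataFrame(x, columns=[f"item{i}" for i in range(1, k + 1)])
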