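import numpy as np
import pytest

from sdcviz import DatasetSpec, PointCloud, generate, reset_noise_registry


@pytest.fixture(autouse=True)
def _fresh_noise_registry():
    """Each test starts with a clean noise-release registry."""
    reset_noise_registry()
    yield
    reset_noise_registry()


@pytest.fixture(scope="session")
def d1():
    """One realization of the normal/linear benchmark dataset (n=500)."""
    return generate(DatasetSpec("D1", 500, 20260928))


@pytest.fixture
def d1_cloud(d1):
    return PointCloud.from_table(d1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cloud(rng, n, scale=1.0):
    """Helper: a generic bivariate cloud with mild correlation."""
    x = rng.normal(0.0, scale, n)
    y = 0.5 * x + rng.normal(0.0, scale, n)
    return PointCloud(x, y)
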