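import numpy as np
import pandas as pd
import pytest

from dcftmle import FAST_LIBRARY, generate_dataset, generate_simple_dataset


@pytest.fixture(scope="session")
def fast_library():
    return FAST_LIBRARY


@pytest.fixture(scope="session")
def main_dataset_3000():
    return generate_dataset(3000, seed=101)


@pytest.fixture(scope="session")
def main_dataset_500():
    return generate_dataset(500, seed=202)


@pytest.fixture(scope="session")
def simple_dataset_large():
    """Simple-mechanism dataset with true marginal risk difference 0.10."""
    return generate_simple_dataset(50_000, seed=303, effect=0.10)


def random_nuisance_fixture(seed: int, n: int = 200):
    """A random but well-behaved targeting problem: binary y, a and interior
    nuisance predictions."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.1, 0.9, size=n)
    q0 = rng.uniform(0.05, 0.95, size=n)
    q1 = rng.uniform(0.05, 0.95, size=n)
    a = rng.binomial(1, g)
    y = rng.binomial(1, np.where(a == 1, q1, q0) * 0.8 + 0.1)
    return y.astype(float), a.astype(float), g, q0, q1
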