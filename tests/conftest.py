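import numpy as np
import pytest

import kaisim as ks


@pytest.fixture(scope="session")
def defaults():
    return ks.default_params()


@pytest.fixture(scope="session")
def small_params(defaults):
    """Desk-scale ensemble preserving all concentrations."""
    return ks.rescale_ensemble(defaults, 50)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distribution(rng: np.random.Generator) -> np.ndarray:
    """A random valid 29-state probability vector."""
    p = rng.dirichlet(np.ones(29) * rng.uniform(0.2, 5.0))
    return p
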