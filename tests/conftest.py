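import numpy as np
import pytest

from modpois import DesignData, SimulationConfig, simulate_network
from modpois.simulate import concatenate_sites, network_model_spec


def make_2x2(n1=20, events1=10, n0=20, events0=5) -> DesignData:
    """Saturated exposure-only dataset: n1 exposed with events1 events, etc."""
    y = np.concatenate(
        [
            np.ones(events1), np.zeros(n1 - events1),
            np.ones(events0), np.zeros(n0 - events0),
        ]
    )
    E = np.concatenate([np.ones(n1), np.zeros(n0)])
    Z = np.column_stack([np.ones(n1 + n0), E])
    return DesignData(Z=Z, y=y)


def random_dataset(rng, n=None, p=None) -> DesignData:
    """Small random log-risk dataset with bounded linear predictors."""
    n = n if n is not None else int(rng.integers(50, 501))
    p = p if p is not None else int(rng.integers(2, 7))
    Z = np.column_stack([np.ones(n)] + [0.5 * rng.normal(size=n) for _ in range(p - 1)])
    beta = rng.normal(scale=0.3, size=p)
    beta[0] = -1.2  # keep risks mostly below 1
    pr = np.minimum(np.exp(Z @ beta), 1.0)
    y = rng.binomial(1, pr).astype(float)
    return DesignData(Z=Z, y=y)


@pytest.fixture(scope="session")
def default_network():
    """One draw of the default 3-partner network (n = 10000)."""
    return simulate_network(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def pooled_default(default_network):
    return concatenate_sites(default_network)


@pytest.fixture(scope="session")
def sim_spec():
    return network_model_spec()
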