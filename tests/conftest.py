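import logging

import numpy as np
import pytest

from gaslc.distributions import Family, FamilySpec
from gaslc.synthetic import ScenarioConfig, make_params, simulate_surface

logging.getLogger("gaslc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def poisson_scene():
    """Small Poisson surface with known truth, shared across tests."""
    params = make_params(8, seed=11)
    config = ScenarioConfig(
        n_ages=8,
        n_years=20,
        params=params,
        family=FamilySpec(Family.POISSON),
        exposure=2e4,
        seed=12,
    )
    surface, kappa = simulate_surface(config)
    return surface, kappa, params


@pytest.fixture(scope="session")
def poisson_fit(poisson_scene):
    """Fitted Poisson model on the shared surface (computed once)."""
    from gaslc import GasLeeCarter

    surface, _, _ = poisson_scene
    return GasLeeCarter(surface, "poisson").fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
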