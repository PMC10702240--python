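import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sfcr import assemble, build_weights, solve_sfcr
from sfcr import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: sigma used when fitting noise-free synthetic data (fractions have no
#: replicate scatter, so a known measurement SD must be supplied)
NOISEFREE_SIGMA = 0.01


@pytest.fixture(scope="session")
def toy5_scenario():
    return syn.toy5()


@pytest.fixture(scope="session")
def minicbc_scenario():
    return syn.mini_cbc()


@pytest.fixture(scope="session")
def toy5_euler(toy5_scenario):
    return syn.euler_propagate(toy5_scenario)


@pytest.fixture(scope="session")
def minicbc_euler(minicbc_scenario):
    return syn.euler_propagate(minicbc_scenario)


def fit_scenario(scenario, dataset, sigma=NOISEFREE_SIGMA, **weight_kwargs):
    """Convenience: weights + assembly + fixed-pool fit for a scenario."""
    if sigma is not None:
        weight_kwargs.setdefault("sigma_override", sigma)
    weights = build_weights(dataset, scenario.spec, **weight_kwargs)
    system = assemble(scenario.spec, dataset, weights, scenario.network,
                      c_params=scenario.c_params)
    return system, solve_sfcr(system, scenario.network, dataset.boundary_fluxes)


@pytest.fixture(scope="session")
def toy5_fit(toy5_scenario, toy5_euler):
    return fit_scenario(toy5_scenario, toy5_euler)


@pytest.fixture(scope="session")
def minicbc_fit(minicbc_scenario, minicbc_euler):
    return fit_scenario(minicbc_scenario, minicbc_euler)
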