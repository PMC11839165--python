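"""Shared fixtures: desk-scale parameter sets and cached deterministic runs."""

import numpy as np
import pytest

import centrosim as cs


@pytest.fixture(scope="session")
def fig3_params():
    """The pinned Fig-3 catalytic scenario (pair growth calibration row)."""
    return cs.load_scenario("fig3c").params


@pytest.fixture(scope="session")
def fig3_pair_network(fig3_params):
    n1, n2 = cs.initial_counts(5e-3, 0.0, fig3_params.delta_v)
    return cs.build_catalytic_network(fig3_params, (n1, n2))


@pytest.fixture(scope="session")
def fig3_pair_ode(fig3_pair_network):
    return cs.simulate_ode(fig3_pair_network, 6000.0)


@pytest.fixture(scope="session")
def fig3_t_read(fig3_pair_ode):
    """Declared steady-state readout time for the Fig-3 scenario."""
    return cs.time_to_steady(fig3_pair_ode)


@pytest.fixture(scope="session")
def small_catalytic_params():
    """Catalytic parameters in a reduced cell volume: same concentrations and
    rates, ~50× fewer molecules — cheap SSA ensembles."""
    return cs.CatalyticParams(
        k_plus=1.0, k_star=2000.0, k1_star=100.0, kE_star=10.0,
        rho0=0.05, E_conc=0.1, Vc=200.0,
    )


@pytest.fixture(scope="session")
def small_autocat_params():
    return cs.AutocatalyticParams.from_concentration(
        0.033, k0_plus=600.0, k1_plus=0.6, Vc=200.0)


@pytest.fixture(scope="session")
def small_two_component_params():
    return cs.TwoComponentParams(rho_a=0.25, rho_b=0.5, rho_E=0.01, Vc=500.0)


def pair_counts(dV0_frac=0.0, V0=5e-3, delta_v=2e-4, assignment="symmetric_split"):
    return cs.initial_counts(V0, dV0_frac * V0, delta_v, assignment)
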