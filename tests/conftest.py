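"""Shared fixtures: configurations and trajectories are session-scoped so
the expensive 504 h integrations run once and are reused across tests."""

import pytest

import thermocomm as tc
from thermocomm.fixtures import DEFAULT_DG_MIN, FixtureOptions, build_dv_mm_mb_system


@pytest.fixture(scope="session")
def species():
    return tc.load_default_species()


@pytest.fixture(scope="session")
def dv_config():
    return build_dv_mm_mb_system(FixtureOptions(cultures=("Dv",)))


@pytest.fixture(scope="session")
def tri_config():
    return build_dv_mm_mb_system(FixtureOptions(cultures=("Dv", "Mm", "Mb")))


@pytest.fixture(scope="session")
def dv_trajectory(dv_config):
    """Dv monoculture, thermodynamics on, lactate fermentation threshold
    -30 kJ/mol (the fixture default), full 504 h horizon."""
    return tc.simulate(dv_config)


@pytest.fixture(scope="session")
def dv_trajectory_no_thermo(dv_config):
    return tc.simulate(dv_config, thermodynamics=False)


@pytest.fixture(scope="session")
def tri_trajectory(tri_config):
    return tc.simulate(tri_config)


@pytest.fixture(scope="session")
def unit_activities(species):
    return {name: 1.0 for name in species}


@pytest.fixture(scope="session")
def dv_truth():
    """Ground-truth thresholds for Dv-monoculture recovery tests: the
    fixture defaults with lactate fermentation moved to -25 kJ/mol."""
    truth = {k: v for k, v in DEFAULT_DG_MIN.items() if k.startswith("Dv")}
    truth["Dv:lactate_fermentation"] = -25.0
    return truth
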