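import numpy as np
import pytest

from nphsim import ScenarioSpec, design_scenario, sample_trial, scenario_grid


@pytest.fixture(scope="session")
def grid():
    return scenario_grid()


@pytest.fixture(scope="session")
def by_id(grid):
    return {s.scenario_id: s for s in grid}


@pytest.fixture(scope="session")
def design_cell() -> ScenarioSpec:
    return design_scenario()


@pytest.fixture(scope="session")
def design_trial(design_cell):
    """One medium trial from the design cell, shared across read-only tests."""
    return sample_trial(design_cell, 42)


@pytest.fixture(scope="session")
def large_ph_trial(design_cell):
    """A large proportional-hazards trial for asymptotic agreement checks."""
    from dataclasses import replace

    scen = replace(design_cell, n_subjects=4000)
    return sample_trial(scen, 7)
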