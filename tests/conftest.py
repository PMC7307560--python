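import numpy as np
import pytest

from boombust import ExperimentDesign, fixture_parameter_sets, solve_trajectory


@pytest.fixture(scope="session")
def fixture_sets():
    return fixture_parameter_sets()


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def dense_grid():
    return np.linspace(0.0, 18.0, 721)


@pytest.fixture(scope="session")
def fixture_trajectories(fixture_sets, design, dense_grid):
    """Dense noiseless trajectories for all six fixture labels."""
    init = design.initial_state
    return {label: solve_trajectory(p, init, dense_grid) for label, p in fixture_sets.items()}
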