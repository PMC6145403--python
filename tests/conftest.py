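import numpy as np
import pytest

from rdinvade import SimulationConfig, build_scenario_grid, run_grid


@pytest.fixture(scope="session")
def default_grid_summaries():
    """Full default scenario grid (29 cells x 500 replicates), run once.

    Master seed 1; shared by the scenario-structure and model-selection
    tests, which only read the summaries.
    """
    grid = build_scenario_grid(n_replicates=500)
    return run_grid(grid, SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
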