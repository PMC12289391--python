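import numpy as np
import pytest

import scrthin as st


@pytest.fixture(scope="session")
def ref_grid():
    """The reference detector array: 8x8 lattice, 800 m spacing."""
    return st.build_detector_grid(8, 8, 800.0)


@pytest.fixture(scope="session")
def ref_space(ref_grid):
    """State space: grid bounding box buffered by 2.5 sigma = 2500 m."""
    return st.build_state_space(ref_grid, 2500.0)


@pytest.fixture(scope="session")
def ref_params():
    return st.DetectionParams(lam0=0.1, sigma=1000.0, K=5)


@pytest.fixture(scope="session")
def ref_config():
    return st.ScenarioConfig(master_seed=123)


@pytest.fixture(scope="session")
def small_dataset(ref_config):
    """One reference-design replicate (population, colonies, control, removed)."""
    from dataclasses import replace

    cfg = replace(ref_config, removal_fraction=0.5)
    return st.generate_replicate(cfg, 0)


@pytest.fixture(scope="session")
def tiny_instance():
    """J=4 detectors, 3 true individuals, K=5: the enumeration-size problem."""
    grid = st.build_detector_grid(2, 2, 800.0)
    space = st.build_state_space(grid, 1000.0)
    params = st.DetectionParams(lam0=0.3, sigma=600.0, K=5)
    pop = st.simulate_activity_centers(3, space, 11)
    y = st.simulate_encounters(pop, grid, params, 12)
    assert y.n_detected >= 1
    return grid, space, params, y
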