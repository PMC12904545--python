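import numpy as np
import pytest

from octspeckle import LayerStack, ParameterGrid, build_map

# study-scale constants shared across the suite: the map uses the default
# 11 x 15 parameter grid at a reduced photon budget of 1e5 packets per
# A-scan (the full 15e6-packet budget is exercised separately where the
# photon-budget benchmarks require it)
REDUCED_BUDGET = 100_000
REDUCED_MAP_SEED = 11


@pytest.fixture(scope="session")
def tiny_map():
    """Small 3 x 3 look-up map for fast structural and matching tests."""
    grid = ParameterGrid(mu_s_values=(0.10, 0.15, 0.20),
                         g_values=(0.85, 0.92, 0.99))
    return build_map(grid, n_packets=50_000, master_seed=3)


@pytest.fixture(scope="session")
def reduced_map():
    """Full 165-entry look-up map at the reduced photon budget."""
    return build_map(n_packets=REDUCED_BUDGET, master_seed=REDUCED_MAP_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
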