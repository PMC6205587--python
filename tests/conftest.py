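import numpy as np
import pytest

from tides.simulate import (EdgeModulationSpec, PanelSpec, constant_coupling,
                            decaying_coupling, simulate_emt_panel,
                            simulate_transient_edge)


@pytest.fixture(scope="session")
def gauss1d():
    return np.random.default_rng(11).normal(0.0, 1.0, 500)


@pytest.fixture(scope="session")
def gauss2d():
    return np.random.default_rng(12).normal(0.0, 1.0, (800, 2))


@pytest.fixture(scope="session")
def gauss3d():
    return np.random.default_rng(13).normal(0.5, np.sqrt(0.3), (1000, 3))


@pytest.fixture(scope="session")
def transient_cells():
    """Strong-but-transient X -> Y edge (decaying coupling)."""
    return simulate_transient_edge(5000, EdgeModulationSpec(coupling=decaying_coupling()), seed=5)


@pytest.fixture(scope="session")
def stationary_cells():
    """X -> Y edge with coupling constant in pseudotime."""
    return simulate_transient_edge(5000, EdgeModulationSpec(coupling=constant_coupling(1.0)), seed=6)


@pytest.fixture(scope="session")
def independent_cells():
    """X and Y independent at all pseudotimes (zero coupling)."""
    return simulate_transient_edge(5000, EdgeModulationSpec(coupling=constant_coupling(0.0)), seed=7)


@pytest.fixture(scope="session")
def emt_panel():
    cells, truth = simulate_emt_panel(PanelSpec(n_cells=3000, seed=8))
    return cells, truth
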