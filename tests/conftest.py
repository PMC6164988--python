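import numpy as np
import pytest

from quantrisk import SimulationConfig, make_lattice_graph, simulate_counts


@pytest.fixture(scope="session")
def lattice_4x4():
    return make_lattice_graph(4, 4)


@pytest.fixture(scope="session")
def lattice_3x3():
    return make_lattice_graph(3, 3)


@pytest.fixture(scope="session")
def recovery_panel(lattice_4x4):
    """One simulated panel on the 4x4 lattice under the study conditions
    (component variances 1/0.2/0.2/0.2, expected counts in [50, 500],
    t errors with df equal to the expected count)."""
    rng = np.random.default_rng(1)
    e = np.exp(rng.uniform(np.log(50), np.log(500), 16))
    cfg = SimulationConfig(
        graph=lattice_4x4, n_times=5, expected_counts=e, n_replicates=1, seed=42
    )
    panels, truth = simulate_counts(cfg)
    return panels[0], truth, lattice_4x4
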