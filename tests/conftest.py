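import numpy as np
import pandas as pd
import pytest

from allokit.synthetic import PlantedSystem, make_scenario, simulate_langevin
from allokit.trajectory import Trajectory


def make_ca_trajectory(coords: np.ndarray,
                       times: np.ndarray | None = None) -> Trajectory:
    """Trajectory of CA pseudo-atoms from a (frames, nodes, 3) array."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[1]
    meta = pd.DataFrame({
        "name": ["CA"] * n,
        "element": ["C"] * n,
        "heavy": [True] * n,
        "resid": np.arange(n, dtype=np.int64),
        "resname": ["GLY"] * n,
        "chain": ["A"] * n,
    })
    if times is None:
        times = np.arange(coords.shape[0], dtype=np.float64)
    return Trajectory(coords, meta, times)


@pytest.fixture(scope="session")
def two_node_system():
    return PlantedSystem(
        n_nodes=2,
        initial_coords=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        edges=[(0, 1)],
        spring_constant={(0, 1): 25.0},
        rest_length={(0, 1): 1.0},
    )


@pytest.fixture(scope="session")
def ten_node_scenario():
    return make_scenario(n_nodes=10, core_region={0, 1, 2},
                         peripheral_regions={"P1": {7, 8, 9}},
                         relay_spec=[], stiffening_factor=4.0,
                         softening_factor=0.25, seed=0)


@pytest.fixture(scope="session")
def short_trajectory(ten_node_scenario):
    return simulate_langevin(ten_node_scenario.apo, n_frames=400, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
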