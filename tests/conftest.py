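import numpy as np
import pytest

from morphodim import dimension, gpa, simulate


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic draw shared across tests."""
    cfg = simulate.SimulationConfig(seed=20)
    ds, truth = simulate.simulate_landmarks(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def one_sided(sim_default):
    """Oriented, side-averaged one-sided 3D and 2D datasets."""
    _, ds, _ = sim_default
    oriented = ds.copy()
    for i in range(ds.n_specimens):
        oriented.coords[i] = dimension.orient_midsagittal(
            ds.coords[i], ds.pairs)
    one3d = gpa.side_average(oriented)
    one2d = dimension.project_dataset(one3d, orient=False)
    return one3d, one2d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
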