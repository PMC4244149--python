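import numpy as np
import pytest

from nichecmp import envspace, synthetic
from nichecmp.grids import EnvGrid


@pytest.fixture(scope="session")
def landscape():
    """A 32x32, 5-layer correlated landscape shared across read-only tests."""
    return synthetic.generate_landscape(32, 32, 5, smoothness=0.3, correlation=0.6, seed=11)


@pytest.fixture(scope="session")
def scenario_divergent():
    return synthetic.generate_scenario("divergent_allopatric", 50, seed=7)


@pytest.fixture(scope="session")
def scenario_sympatric():
    return synthetic.generate_scenario("sympatric_shared", 50, seed=7)


@pytest.fixture(scope="session")
def scenario_conserved():
    return synthetic.generate_scenario("conserved_allopatric", 50, seed=7)


@pytest.fixture(scope="session")
def pc_layers(scenario_divergent):
    """Component-score layers for the divergent scenario's grid."""
    model = envspace.fit_pca(scenario_divergent.grid)
    k = envspace.select_components(model, 0.97)
    return envspace.project_grid(scenario_divergent.grid, model, k)


def tiny_grid(values, cell_size=1.0, origin=(0.0, 10.0), names=None, nodata=None):
    """Helper building a small EnvGrid from a (layers, rows, cols) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    names = names or [f"env{i + 1}" for i in range(values.shape[0])]
    return EnvGrid(values=values, layer_names=names, cell_size=cell_size,
                   origin=origin, nodata_mask=nodata)
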