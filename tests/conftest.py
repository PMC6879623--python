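import numpy as np
import pytest

from colonymorph import SyntheticSpec, delaunay_graph, generate_colony


@pytest.fixture()
def rng():
    return np.random.default_rng(20190911)


@pytest.fixture(scope="session")
def mixed_colony():
    """A 400-cell jittered-lattice colony with randomly mixed cell sizes."""
    colony, labels = generate_colony(SyntheticSpec(n_cells=400, seed=11))
    return colony, labels


@pytest.fixture(scope="session")
def clustered_colony():
    """A 600-cell colony whose small cells are concentrated in patches."""
    colony, labels = generate_colony(SyntheticSpec(
        n_cells=600, label_pattern="clustered", cluster_strength=0.8, seed=7))
    return colony, labels


@pytest.fixture(scope="session")
def mixed_graph(mixed_colony):
    colony, _ = mixed_colony
    return delaunay_graph(colony.centroids)


@pytest.fixture(scope="session")
def clustered_graph(clustered_colony):
    colony, _ = clustered_colony
    return delaunay_graph(colony.centroids)
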