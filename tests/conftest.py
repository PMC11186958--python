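import numpy as np
import pytest

from popergm.netstats import Graph, StatisticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def triangle():
    return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def k4():
    return Graph.complete(4)


@pytest.fixture
def path3():
    return Graph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def edges_spec():
    return StatisticSpec.from_strings(["edges"])


@pytest.fixture
def edges_gwesp_spec():
    return StatisticSpec.from_strings(["edges", "gwesp(0.9)"])


def random_graph(n, density, rng, hemisphere=None, homotopy_partner=None):
    """Erdos-Renyi helper shared across test modules."""
    upper = np.triu((rng.random((n, n)) < density).astype(np.int8), k=1)
    return Graph(upper + upper.T, hemisphere, homotopy_partner)


def two_hemisphere_attrs(n):
    half = n // 2
    hemi = np.array(["L"] * half + ["R"] * half)
    partner = np.concatenate([np.arange(half) + half, np.arange(half)])
    return hemi, partner
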