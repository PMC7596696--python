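"""Shared fixtures: small hand-built networks and the honeycomb test case."""

import numpy as np
import pytest
from hypothesis import settings

from vasoadapt.netgraph import HexagonalLattice, VascularNetwork

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_network(
    edges,
    n_nodes,
    fixed_pressures,
    diameters=None,
    lengths=None,
    ht_in=None,
    coords=None,
):
    """Build a VascularNetwork from a terse description.

    ``fixed_pressures`` maps node index -> pressure (Pa); ``ht_in`` maps
    node index -> inflow tube haematocrit.
    """
    edges = np.asarray(edges)
    ne = len(edges)
    pressure = np.full(n_nodes, np.nan)
    boundary = np.zeros(n_nodes, dtype=bool)
    for n, p in fixed_pressures.items():
        pressure[n] = p
        boundary[n] = True
    ht = np.full(n_nodes, np.nan)
    for n, h in (ht_in or {}).items():
        ht[n] = h
        boundary[n] = True
    return VascularNetwork(
        node_ids=np.arange(n_nodes),
        coords=coords if coords is not None else np.full((n_nodes, 3), np.nan),
        boundary=boundary,
        pressure=pressure,
        ht_in=ht,
        edge_ids=np.arange(ne),
        edge_nodes=edges,
        diameter=diameters if diameters is not None else np.full(ne, 4.5),
        length=lengths if lengths is not None else np.full(ne, 75.0),
        edge_type=np.full(ne, "", dtype=object),
    )


@pytest.fixture
def single_edge_network():
    """One vessel between two fixed-pressure nodes."""
    return make_network([[0, 1]], 2, {0: 100.0, 1: 0.0})


@pytest.fixture
def parallel_edges_network():
    """Two identical vessels between the same node pair."""
    return make_network([[0, 1], [0, 1]], 2, {0: 100.0, 1: 0.0})


@pytest.fixture
def y_network():
    """Divergent bifurcation: inlet edge splitting into two daughters."""
    return make_network(
        [[0, 1], [1, 2], [1, 3]],
        4,
        {0: 200.0, 2: 0.0, 3: 0.0},
        ht_in={0: 0.3},
    )


@pytest.fixture
def mesh_network():
    """17-edge, 12-node loopy network with three boundary nodes."""
    rng = np.random.default_rng(42)
    edges = [
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (1, 6), (6, 7),
        (7, 2), (7, 8), (8, 9), (9, 3), (9, 10), (10, 11), (11, 4),
        (6, 10), (8, 11),
    ]
    return make_network(
        edges,
        12,
        {0: 200.0, 5: 150.0, 11: 0.0},
        diameters=rng.uniform(3.5, 7.0, len(edges)),
        lengths=rng.uniform(40.0, 110.0, len(edges)),
    )


@pytest.fixture(scope="session")
def hex_lattice():
    return HexagonalLattice(9, 9, d0=4.5, l=75.0)


@pytest.fixture(scope="session")
def hex_network(hex_lattice):
    return hex_lattice.network()


@pytest.fixture(scope="session")
def hex_activated(hex_lattice):
    return hex_lattice.central_flower_edges()
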