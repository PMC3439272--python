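"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from edgeflux.network import Edge, InteractionNetwork
from edgeflux.walk import TransitionMatrix, build_transition_matrix


def dense_stationary(tm: TransitionMatrix, weights: dict, q: float) -> np.ndarray:
    """Independent oracle: solve the stationary distribution as a dense
    linear system g(M - I) = 0, sum(g) = 1, with dangling rows replaced by
    the restart distribution.  No power iteration involved."""
    n = tm.n
    P = tm.P.toarray()
    r = np.array([weights[node] for node in tm.nodes], dtype=float)
    r = r / r.sum()
    P[tm.dangling] = r
    M = (1.0 - q) * P + q * np.outer(np.ones(n), r)
    A = M.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    return np.linalg.solve(A, b)


def dense_edge_probabilities(net: InteractionNetwork, weights: dict,
                             q: float) -> dict[tuple[str, str], float]:
    """Arc probabilities e_ij = g_i p_ij from the dense-solve oracle."""
    tm = build_transition_matrix(net, weights)
    g = dense_stationary(tm, weights, q)
    coo = tm.P.tocoo()
    return {(tm.nodes[i], tm.nodes[j]): float(g[i] * p)
            for i, j, p in zip(coo.row, coo.col, coo.data)}


def random_mixed_network(rng: np.random.Generator, n_nodes: int = 50,
                         n_edges: int = 120, p_directed: float = 0.4,
                         allow_isolated: bool = True) -> tuple[InteractionNetwork, dict]:
    """Random graph mixing directed and undirected edges; isolated nodes
    (dangling in the walk) are kept when allow_isolated."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    edges = []
    for _ in range(n_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        edges.append(Edge(names[i], names[j],
                          directed=bool(rng.random() < p_directed)))
    nodes = names if allow_isolated else []
    net = InteractionNetwork(edges, nodes=nodes)
    weights = {nm: float(rng.uniform(0.2, 5.0)) for nm in net.nodes}
    return net, weights


@pytest.fixture
def two_node_network() -> InteractionNetwork:
    """The analytic case: one undirected edge A--B."""
    return InteractionNetwork([Edge("A", "B", directed=False)])


@pytest.fixture
def path_network() -> InteractionNetwork:
    """Undirected path A--B--C."""
    return InteractionNetwork([Edge("A", "B"), Edge("B", "C")])


@pytest.fixture(scope="session")
def planted_bundle():
    """One default planted scenario shared across tests (seed 0)."""
    from edgeflux.synthetic import generate_scenario
    return generate_scenario(seed=0)
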