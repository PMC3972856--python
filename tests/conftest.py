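"""Shared graph fixtures: all tiny, constructed programmatically."""

import networkx as nx
import pytest


def as_str(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {x: str(x) for x in g.nodes()})


@pytest.fixture
def path3() -> nx.Graph:
    """Path a-b-c."""
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star5() -> nx.Graph:
    """Star: center h with 4 leaves."""
    return nx.Graph([("h", "l1"), ("h", "l2"), ("h", "l3"), ("h", "l4")])


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint triangles {a,b,c} and {d,e,f}."""
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    )


@pytest.fixture
def bridged_triangles(two_triangles) -> nx.Graph:
    """Two triangles joined by the single bridge edge c-d (m = 7)."""
    g = two_triangles.copy()
    g.add_edge("c", "d")
    return g


@pytest.fixture
def k_example_graph() -> nx.Graph:
    """10-edge graph where node 'i' (degree 4, cluster {i,a,b,c}) has K = 4.

    m = 10, d = 20; d_i = 4, m_i = 3 (edges to a, b, c), cluster degree sum
    d_q = 4 + 2 + 2 + 2 = 10, hence
    K = 3 / ((4/20) * ((10-4)/(20-4)) * 10) = 3 / 0.75 = 4.
    """
    return nx.Graph(
        [
            ("i", "a"), ("i", "b"), ("i", "c"), ("i", "x"),
            ("a", "b"), ("c", "y"),
            ("x", "y"), ("x", "z"), ("y", "z"), ("z", "w"),
        ]
    )


@pytest.fixture
def k_example_assignment() -> dict:
    return {"i": 1, "a": 1, "b": 1, "c": 1, "x": 2, "y": 2, "z": 2, "w": 2}


def random_graphs(n_graphs: int, n_max: int, seed: int = 0, connected: bool = False):
    """Deterministic stream of small random graphs with string labels."""
    import random

    rng = random.Random(seed)
    out = []
    while len(out) < n_graphs:
        n = rng.randint(3, n_max)
        p = rng.uniform(0.2, 0.9)
        g = as_str(nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1)))
        if connected and not (g.number_of_nodes() and nx.is_connected(g)):
            continue
        out.append(g)
    return out
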