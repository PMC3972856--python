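"""Per-node metrics: betweenness centrality, local clustering, core influence.

Core influence amplifies a node's (normalized) betweenness centrality by the
sparseness of its immediate neighborhood:

    C_A(x) = C_B(x) / c~_x,    c~_x = 2 * max(E_x, 1) / (k_x * (k_x - 1))

where k_x is the degree of x and E_x the number of edges among its
neighbors.  A high-betweenness node whose neighbors are poorly
interconnected brokers the traffic of its region and scores high.  E_x is
floored at 1 inside the denominator so the score stays finite for nodes
whose neighborhood contains no edges at all; nodes of degree < 2 score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    degree: int
    neighbor_edges: int
    local_clustering: float
    betweenness: float
    core_influence: float


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Normalized shortest-path betweenness centrality for every node.

    C_B(x) is the fraction of all-pairs geodesics with x interior, scaled by
    2/((n-1)(n-2)) so values lie in [0, 1].  Endpoints are excluded from
    their own counts and disconnected pairs contribute nothing.  Computed by
    Brandes dependency accumulation over BFS shortest-path DAGs, O(nm).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("betweenness_centrality requires a nonempty graph")
    if g.number_of_nodes() < 3:
        return {x: 0.0 for x in g.nodes()}
    return nx.betweenness_centrality(g, normalized=True)


def local_clustering(g: nx.Graph, x: str) -> tuple[int, int, float]:
    """Return (k_x, E_x, c_x) for node x.

    E_x counts edges both of whose endpoints are neighbors of x; the local
    clustering coefficient c_x = 2 E_x / (k_x (k_x - 1)) for k_x >= 2, else 0.
    """
    if x not in g:
        raise KeyError(f"node {x!r} not in graph")
    k = g.degree(x)
    e_x = nx.triangles(g, x)
    c = 2.0 * e_x / (k * (k - 1)) if k >= 2 else 0.0
    return k, e_x, c


def core_influence(g: nx.Graph, betweenness: dict[str, float] | None = None) -> dict[str, float]:
    """Core influence C_A for every node (see module docstring).

    ``betweenness`` may be passed in to avoid recomputation.
    """
    if betweenness is None:
        betweenness = betweenness_centrality(g)
    triangles = nx.triangles(g)
    ca: dict[str, float] = {}
    for x in g.nodes():
        k = g.degree(x)
        if k < 2:
            ca[x] = 0.0
            continue
        c_floor = 2.0 * max(triangles[x], 1) / (k * (k - 1))
        ca[x] = betweenness[x] / c_floor
    return ca


def compute_node_metrics(g: nx.Graph) -> dict[str, NodeMetrics]:
    """All per-node metrics in one pass (one betweenness computation)."""
    cb = betweenness_centrality(g)
    triangles = nx.triangles(g)
    ca = core_influence(g, betweenness=cb)
    out: dict[str, NodeMetrics] = {}
    for x in g.nodes():
        k = g.degree(x)
        e_x = triangles[x]
        c = 2.0 * e_x / (k * (k - 1)) if k >= 2 else 0.0
        out[x] = NodeMetrics(
            node=x,
            degree=k,
            neighbor_edges=e_x,
            local_clustering=c,
            betweenness=cb[x],
            core_influence=ca[x],
        )
    return out
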