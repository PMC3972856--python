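"""Candidate-core selection and the K-function core test.

A node qualifies to found its own cluster when the K function — the ratio of
its actual connections into its current cluster to the connections expected
under random wiring —

    K(i) = m_i / [ (d_i / d) * ((d_q - d_i) / (d - d_i)) * m ]

falls inside a fixed interval (default [1.96, 2.71]).  Here m_i is the number
of edges between node i and other members of its cluster, d_i its degree,
d_q the degree sum of its cluster (node included), d the degree sum of the
whole graph and m the total edge count.  When the whole connected graph is a
single cluster, K(i) = 2 exactly for every node (d = 2m), which anchors the
interval around 2.

Candidates are the top fraction of nodes (default 20%, the Pareto rule) under
the ordering key: core influence descending, degree descending, label
ascending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from coreclust.node_metrics import NodeMetrics

ORDER_KEYS = ("ca", "betweenness", "degree")


@dataclass(frozen=True)
class CoreParams:
    """Tunable constants of the core test.

    k_low/k_high bound the closed acceptance interval of the K function;
    core_fraction is the share of nodes eligible as candidate cores.
    """

    k_low: float = 1.96
    k_high: float = 2.71
    core_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.k_low <= self.k_high):
            raise ValueError(f"require 0 < k_low <= k_high, got [{self.k_low}, {self.k_high}]")
        if not (0 < self.core_fraction <= 1):
            raise ValueError(f"core_fraction must be in (0, 1], got {self.core_fraction}")


@dataclass(frozen=True)
class KEvaluation:
    """The six quantities entering the K function plus its value."""

    node: str
    m_i: int
    d_i: int
    d_q: int
    d: int
    m: int
    k_value: float


def k_function(g: nx.Graph, assignment: Mapping[str, int], node: str) -> KEvaluation:
    """Evaluate the K function for ``node`` against its current cluster.

    Degenerate states — the node carrying all degree (d_i = d) or being the
    sole degree in its cluster (d_q = d_i) — yield K = 0: such a node cannot
    found a new cluster.

    Raises
    ------
    KeyError
        If the node has no cluster assignment.
    """
    if node not in assignment:
        raise KeyError(f"node {node!r} is not assigned to any cluster")
    cid = assignment[node]
    members = {x for x, c in assignment.items() if c == cid}
    m = g.number_of_edges()
    d = 2 * m
    d_i = g.degree(node)
    m_i = sum(1 for nb in g.adj[node] if nb in members and nb != node)
    d_q = sum(g.degree(x) for x in members)
    if m == 0 or d_i == 0 or d_i == d or d_q == d_i:
        k_value = 0.0
    else:
        expected = (d_i / d) * ((d_q - d_i) / (d - d_i)) * m
        k_value = m_i / expected if expected > 0 else 0.0
    return KEvaluation(node=node, m_i=m_i, d_i=d_i, d_q=d_q, d=d, m=m, k_value=k_value)


def is_core_eligible(k: KEvaluation, p: CoreParams) -> bool:
    """True iff the K value lies in the closed interval [k_low, k_high]."""
    return p.k_low <= k.k_value <= p.k_high


def candidate_cores(
    metrics: Mapping[str, NodeMetrics],
    p: CoreParams,
    order: str = "ca",
) -> list[str]:
    """The top ceil(core_fraction * n) nodes under the chosen ordering.

    ``order`` selects the primary key: "ca" (core influence, default),
    "betweenness", or "degree".  Ties break by degree descending then label
    ascending, so the output is deterministic.
    """
    if order not in ORDER_KEYS:
        raise ValueError(f"order must be one of {ORDER_KEYS}, got {order!r}")
    if order == "ca":
        key = lambda x: (-metrics[x].core_influence, -metrics[x].degree, x)
    elif order == "betweenness":
        key = lambda x: (-metrics[x].betweenness, -metrics[x].degree, x)
    else:
        key = lambda x: (-metrics[x].degree, x)
    n = len(metrics)
    n_cand = math.ceil(p.core_fraction * n)
    return sorted(metrics, key=key)[:n_cand]
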