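"""Greedy modularity-maximization baseline (agglomerative, Newman-style).

Starts from singleton communities and repeatedly merges the connected pair of
communities giving the largest modularity gain,

    dQ(i, j) = m_ij / m - 2 * (d_i / 2m) * (d_j / 2m),

recording Q after every merge and returning the partition at the peak.  Ties
on dQ break on the lexicographically smallest pair of community ids, so runs
are fully deterministic.  Pairs with no connecting edge are never proposed
(merging them can only decrease Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from coreclust.influence_clustering import Partition


def modularity(g: nx.Graph, assignment: Mapping[str, int]) -> float:
    """Newman modularity Q = sum_c [ m_c/m - (d_c/2m)^2 ].

    m_c is the intra-cluster edge count and d_c the degree sum of cluster c.

    Raises
    ------
    ValueError
        If the graph has no edges or the assignment misses a node.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    missing = [x for x in g.nodes() if x not in assignment]
    if missing:
        raise ValueError(f"assignment misses node(s): {sorted(missing)[:5]}")
    intra: dict[int, int] = {}
    deg: dict[int, int] = {}
    for x in g.nodes():
        deg[assignment[x]] = deg.get(assignment[x], 0) + g.degree(x)
    for u, v in g.edges():
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    return sum(
        intra.get(c, 0) / m - (d / (2 * m)) ** 2 for c, d in deg.items()
    )


@dataclass
class FNResult:
    """Outcome of a greedy-modularity run."""

    partition: Partition
    q: float | None  # peak modularity (None on an edgeless graph)
    q_trace: list[float] = field(default_factory=list)  # Q after each merge
    merges: list[tuple[int, int]] = field(default_factory=list)  # (absorbed, into)


def fast_newman(g: nx.Graph) -> FNResult:
    """Greedy modularity agglomeration; returns the partition at peak Q.

    On an edgeless graph every node becomes a singleton and ``q`` is None.
    The recorded trace starts from the all-singleton state, so the returned
    Q is never below that baseline.
    """
    nodes = sorted(g.nodes())
    comm_of = {x: i + 1 for i, x in enumerate(nodes)}
    m = g.number_of_edges()
    if m == 0:
        part = Partition(
            assignment=dict(comm_of),
            cores={},
            states={x: "P" for x in nodes},
        )
        return FNResult(partition=part, q=None)

    deg = {comm_of[x]: g.degree(x) for x in nodes}
    intra = {cid: 0 for cid in deg}
    # edge counts between community pairs, keyed by sorted id pair
    between: dict[tuple[int, int], int] = {}
    for u, v in g.edges():
        key = tuple(sorted((comm_of[u], comm_of[v])))
        between[key] = between.get(key, 0) + 1

    def q_now() -> float:
        return sum(intra[c] / m - (deg[c] / (2 * m)) ** 2 for c in deg)

    states = [dict(comm_of)]
    q_trace = [q_now()]
    merges: list[tuple[int, int]] = []

    while between:
        two_m = 2 * m
        best_key = None
        best_pair = None
        for (i, j), e_ij in between.items():
            dq = e_ij / m - 2 * (deg[i] / two_m) * (deg[j] / two_m)
            key = (round(dq, 14), -i, -j)  # ties: smallest id pair
            if best_key is None or key > best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair  # absorb j into i (i < j)
        intra[i] += intra.pop(j) + between.pop((i, j))
        deg[i] += deg.pop(j)
        # re-route j's remaining connections to i
        for (a, b), e in list(between.items()):
            if j in (a, b):
                other = a if b == j else b
                del between[(a, b)]
                nk = tuple(sorted((i, other)))
                between[nk] = between.get(nk, 0) + e
        for x, c in comm_of.items():
            if c == j:
                comm_of[x] = i
        merges.append((j, i))
        states.append(dict(comm_of))
        q_trace.append(q_now())

    peak = max(range(len(q_trace)), key=lambda idx: q_trace[idx])
    best_assignment = states[peak]
    # relabel cluster ids to consecutive positive integers by member order
    relabel: dict[int, int] = {}
    final: dict[str, int] = {}
    for x in nodes:
        c = best_assignment[x]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        final[x] = relabel[c]
    part = Partition(assignment=final, cores={}, states={x: "P" for x in nodes})
    return FNResult(partition=part, q=q_trace[peak], q_trace=q_trace, merges=merges)
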