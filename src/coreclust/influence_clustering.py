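"""Seed-and-expand clustering driven by core influence and centralization.

The algorithm seeds clusters from high core-influence candidate nodes, tracks
every node through three states — P (clustered), Q (unclustered), R
(contested) — and resolves contested and leftover nodes by maximizing the
summed per-cluster *centralization*:

    C_A^g = sum_x (C_A* - C_A(x)) / ((n - 1) * max_x (C_A* - C_A(x)))

over a cluster's members, where C_A* is the cluster's maximum core influence.
A uniform profile scores 0 (no core), a one-hot profile scores 1 (perfectly
centralized).  C_A values come from ONE global computation on the full graph
and are never recomputed on subgraphs: the assignment pass is bookkeeping,
not a re-derivation.

Run outline (deterministic throughout — no randomness anywhere):

1. Compute node metrics and order candidate cores (top ``core_fraction``
   by core influence; ties by degree, then label).
2. All nodes start in Q.
3. The first candidate founds cluster 1 together with all its neighbors.
4. Each later candidate founds a new cluster if it is still unclustered;
   if already clustered, it founds one only when its K value falls inside
   [k_low, k_high], otherwise its unclustered neighbors join its cluster.
5. Founding pulls the core's Q-neighbors into the new cluster and pushes its
   P-neighbors from other clusters into R (they keep their provisional
   assignment); contested nodes are then re-assigned, highest core influence
   first, to the neighboring cluster that maximizes total centralization.
6. After the candidates are exhausted, remaining Q nodes are absorbed in
   frontier sweeps; nodes with no clustered neighbor become singletons; a
   final refinement sweep re-runs the centralization assignment over all
   non-core nodes until a fixed point (capped at ``max_iter`` sweeps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from coreclust.core_detection import CoreParams, candidate_cores, is_core_eligible, k_function
from coreclust.node_metrics import compute_node_metrics

log = logging.getLogger(__name__)

# states
P, Q, R = "P", "Q", "R"

# rounding applied to centralization sums before comparison, so that
# float noise does not override the documented tie-breaks
_TIE_DECIMALS = 12


class DeferAssignment(Exception):
    """Raised when a node has no clustered neighbor and cannot be placed yet."""


@dataclass
class Partition:
    """A (possibly mid-run) clustering with P/Q/R node states.

    ``assignment`` maps nodes to positive integer cluster ids; nodes in R keep
    their provisional previous assignment, nodes in Q have none.  ``cores``
    maps each founded cluster to its immovable core node.
    """

    assignment: dict[str, int] = field(default_factory=dict)
    cores: dict[int, str] = field(default_factory=dict)
    states: dict[str, str] = field(default_factory=dict)

    def clusters(self) -> dict[int, set[str]]:
        """Cluster id -> member set, derived from the assignment."""
        out: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def centralization(ca_values: Iterable[float]) -> float:
    """Centralization of one cluster's core-influence profile; in [0, 1].

    0 for a singleton or a uniform profile, 1 for a one-hot profile.
    """
    values = list(ca_values)
    if not values:
        raise ValueError("centralization requires a nonempty profile")
    n = len(values)
    if n == 1:
        return 0.0
    c_star = max(values)
    gaps = [c_star - v for v in values]
    d = max(gaps)
    if d == 0:
        return 0.0
    return sum(gaps) / ((n - 1) * d)


def total_centralization(partition: Partition, ca: Mapping[str, float]) -> float:
    """Sum of per-cluster centralization over all nonempty clusters."""
    return sum(
        centralization([ca[x] for x in members]) for members in partition.clusters().values()
    )


def _choose_cluster(
    node: str,
    partition: Partition,
    g: nx.Graph,
    ca: Mapping[str, float],
    members: dict[int, set[str]],
) -> int:
    """Pick the neighboring cluster for ``node`` that maximizes the summed
    centralization over all affected clusters.

    Candidates are the clusters holding at least one P-state neighbor.  Ties
    break by more edges from the node into the cluster, then smaller cluster
    id.  Raises :class:`DeferAssignment` when no neighbor is clustered.
    """
    cand_ids = sorted(
        {
            partition.assignment[nb]
            for nb in g.adj[node]
            if partition.states.get(nb) == P
        }
    )
    if not cand_ids:
        raise DeferAssignment(node)
    prev = partition.assignment.get(node)
    affected = set(cand_ids)
    if prev is not None:
        affected.add(prev)

    def objective(target: int) -> float:
        total = 0.0
        for cid in affected:
            mem = set(members.get(cid, ()))
            mem.discard(node)
            if cid == target:
                mem.add(node)
            if mem:
                total += centralization([ca[x] for x in mem])
        return total

    best = None
    for cid in cand_ids:
        edges_in = sum(
            1 for nb in g.adj[node] if partition.assignment.get(nb) == cid and nb != node
        )
        key = (round(objective(cid), _TIE_DECIMALS), edges_in, -cid)
        if best is None or key > best[0]:
            best = (key, cid)
    return best[1]


def assign_contested(
    node: str,
    partition: Partition,
    g: nx.Graph,
    ca: Mapping[str, float],
) -> int:
    """Resolve a contested or unclustered node and move it to state P.

    Returns the chosen cluster id; the partition is updated in place.  Raises
    :class:`DeferAssignment` when the node has no clustered neighbor.
    """
    members = partition.clusters()
    cid = _choose_cluster(node, partition, g, ca, members)
    partition.assignment[node] = cid
    partition.states[node] = P
    return cid


class _Run:
    """Mutable state of one clustering run (keeps member sets incremental)."""

    def __init__(self, g: nx.Graph, ca: Mapping[str, float], validate: bool):
        self.g = g
        self.ca = ca
        self.validate = validate
        self.partition = Partition(states={x: Q for x in g.nodes()})
        self.members: dict[int, set[str]] = {}
        self.next_cid = 1
        self.founding_events = 0
        self.sweeps = 0

    # -- bookkeeping ------------------------------------------------------
    def _check(self) -> None:
        if not self.validate:
            return
        st = self.partition.states
        counts = {s: sum(1 for v in st.values() if v == s) for s in (P, Q, R)}
        assert sum(counts.values()) == self.g.number_of_nodes(), "P/Q/R must partition the nodes"
        for x, s in st.items():
            if s == Q:
                assert x not in self.partition.assignment
            else:
                assert x in self.partition.assignment

    def _move(self, node: str, cid: int, state: str) -> None:
        prev = self.partition.assignment.get(node)
        if prev is not None and prev != cid:
            self.members[prev].discard(node)
            if not self.members[prev]:
                del self.members[prev]
        self.partition.assignment[node] = cid
        self.members.setdefault(cid, set()).add(node)
        self.partition.states[node] = state

    def ca_order(self, nodes: Iterable[str]) -> list[str]:
        return sorted(nodes, key=lambda x: (-self.ca[x], -self.g.degree(x), x))

    # -- algorithm events --------------------------------------------------
    def found_cluster(self, core: str, absorb_neighbors: bool = True) -> int:
        """Found a new cluster with ``core`` as its immovable core node."""
        cid = self.next_cid
        self.next_cid += 1
        self.founding_events += 1
        self._move(core, cid, P)
        self.partition.cores[cid] = core
        if absorb_neighbors:
            for nb in sorted(self.g.adj[core]):
                state = self.partition.states[nb]
                if state == Q:
                    self._move(nb, cid, P)
                elif (
                    state == P
                    and self.partition.assignment[nb] != cid
                    and nb not in self.partition.cores.values()
                ):
                    # contested: keeps its provisional assignment
                    self.partition.states[nb] = R
        self._check()
        return cid

    def resolve_contested(self) -> None:
        """Re-assign every R node, highest core influence first."""
        guard = 0
        while True:
            r_nodes = self.ca_order(x for x, s in self.partition.states.items() if s == R)
            if not r_nodes:
                return
            progress = False
            for x in r_nodes:
                try:
                    cid = self._choose(x)
                except DeferAssignment:
                    continue
                self._move(x, cid, P)
                progress = True
                self._check()
            guard += 1
            if not progress or guard > len(self.partition.states):
                # an R node with no clustered neighbor reverts to its
                # provisional cluster (cannot happen for core-adjacent nodes,
                # defensive for pathological graphs)
                for x in r_nodes:
                    if self.partition.states[x] == R:
                        self.partition.states[x] = P
                self._check()
                return

    def _choose(self, node: str) -> int:
        return _choose_cluster(node, self.partition, self.g, self.ca, self.members)


def cluster(
    g: nx.Graph,
    params: CoreParams | None = None,
    max_iter: int = 100,
    order: str = "ca",
    validate: bool = False,
) -> tuple[Partition, dict]:
    """Cluster a graph by core influence; see the module docstring.

    Parameters
    ----------
    g : undirected simple graph, nonempty
    params : K interval and candidate fraction (defaults 1.96, 2.71, 0.20)
    max_iter : cap on resolution/refinement sweeps
    order : candidate ordering key ("ca", "betweenness" or "degree")
    validate : assert P/Q/R state conservation after every algorithm event

    Returns
    -------
    (partition, report) where report holds n_clusters, founding_events,
    sweeps, per-cluster sizes and core labels.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cluster requires a nonempty graph")
    params = params or CoreParams()
    metrics = compute_node_metrics(g)
    ca = {x: m.core_influence for x, m in metrics.items()}
    candidates = candidate_cores(metrics, params, order=order)

    run = _Run(g, ca, validate)
    part = run.partition

    # first candidate founds cluster 1 unconditionally
    run.found_cluster(candidates[0])
    run.resolve_contested()

    for cand in candidates[1:]:
        if part.states[cand] != P:
            run.found_cluster(cand)
            run.resolve_contested()
        elif cand in part.cores.values():
            continue  # already heads a cluster
        else:
            kev = k_function(g, part.assignment, cand)
            if is_core_eligible(kev, params):
                run.found_cluster(cand)
                run.resolve_contested()
            else:
                cid = part.assignment[cand]
                for nb in sorted(g.adj[cand]):
                    if part.states[nb] == Q:
                        run._move(nb, cid, P)
                run._check()

    # frontier sweeps: absorb remaining unclustered nodes; whenever no Q node
    # touches a cluster (separate component, isolated vertex), the best
    # remaining Q node founds a new cluster exactly like the first candidate
    while any(s == Q for s in part.states.values()):
        q_nodes = run.ca_order(x for x, s in part.states.items() if s == Q)
        progress = False
        for x in q_nodes:
            if part.states[x] != Q:
                continue
            try:
                cid = run._choose(x)
            except DeferAssignment:
                continue
            run._move(x, cid, P)
            progress = True
            run._check()
        run.sweeps += 1
        if not progress:
            leftover = run.ca_order(x for x, s in part.states.items() if s == Q)
            run.found_cluster(leftover[0])
            run.resolve_contested()
        if run.sweeps > max_iter + g.number_of_nodes():
            log.warning("frontier phase exceeded sweep cap; forcing singletons")
            for x in sorted(x for x, s in part.states.items() if s == Q):
                run.found_cluster(x, absorb_neighbors=False)
            break

    # final refinement: re-run the centralization assignment over all
    # non-core nodes until a fixed point
    core_nodes = set(part.cores.values())
    for _ in range(max_iter):
        changed = False
        for x in run.ca_order(g.nodes()):
            if x in core_nodes:
                continue
            try:
                cid = run._choose(x)
            except DeferAssignment:
                continue
            if cid != part.assignment[x]:
                run._move(x, cid, P)
                changed = True
                run._check()
        run.sweeps += 1
        if not changed:
            break
    else:
        log.warning("refinement did not converge within max_iter=%d sweeps", max_iter)

    sizes = {cid: len(m) for cid, m in part.clusters().items()}
    report = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_clusters": len(sizes),
        "founding_events": run.founding_events,
        "sweeps": run.sweeps,
        "cluster_sizes": {str(k): v for k, v in sorted(sizes.items())},
        "cores": {str(cid): core for cid, core in sorted(part.cores.items()) if cid in sizes},
    }
    return part, report
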