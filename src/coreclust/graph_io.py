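"""Graph and partition I/O plus descriptive network statistics.

Graphs are plain :class:`networkx.Graph` objects with string node labels.
Every reader returns an undirected simple graph: directed inputs are
symmetrized, self-loops dropped, duplicate edges collapsed.  Partitions are
two-column TSV files (node label, integer cluster id).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx

log = logging.getLogger(__name__)

_COMMENT_PREFIXES = ("#", "%")


class GraphFormatError(ValueError):
    """A graph file violates its format (malformed line, dangling edge id)."""


class PartitionIntegrityError(ValueError):
    """A partition is inconsistent with its graph (missing or duplicate node)."""


def read_edge_list(
    path: str | Path,
    symmetrize: bool = True,
    drop_self_loops: bool = True,
) -> nx.Graph:
    """Read a whitespace-delimited edge list into an undirected simple graph.

    Lines starting with ``#`` or ``%`` and blank lines are skipped.  Each
    remaining line must carry at least two tokens (source, target); extra
    tokens are ignored.  Duplicate edges collapse to one.  ``symmetrize`` is
    accepted for interface symmetry with directed formats; the result is
    always undirected.

    Raises
    ------
    GraphFormatError
        If a non-comment line has fewer than two tokens, or a self-loop is
        encountered with ``drop_self_loops=False``.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                if drop_self_loops:
                    n_loops += 1
                    continue
                raise GraphFormatError(f"{path}: line {lineno}: self-loop on {u!r}")
            g.add_edge(u, v)
    if n_loops:
        log.info("dropped %d self-loop line(s) from %s", n_loops, path)
    return g


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML file into an undirected simple graph.

    Node names come from the ``label`` key when present, else the stringified
    ``id``.  Directed GML is symmetrized; self-loops are dropped.

    Raises
    ------
    GraphFormatError
        On missing node ids or edges referencing unknown ids.
    """
    try:
        raw = nx.read_gml(str(path), label="id")
    except nx.NetworkXError as exc:
        raise GraphFormatError(f"{path}: {exc}") from exc
    mapping = {}
    for node, data in raw.nodes(data=True):
        label = data.get("label")
        mapping[node] = str(label) if label is not None else str(node)
    g = nx.Graph()
    g.add_nodes_from(mapping.values())
    for u, v in raw.edges():
        if mapping[u] != mapping[v]:
            g.add_edge(mapping[u], mapping[v])
    return g


def write_partition(
    partition: Mapping[str, int] | "object",
    path: str | Path,
    nodes=None,
) -> None:
    """Write a partition as TSV rows ``node<TAB>cluster`` sorted by node label.

    ``partition`` is either a node -> cluster-id mapping or any object with an
    ``assignment`` attribute holding one.  When ``nodes`` is given, every node
    in it must be assigned.

    Raises
    ------
    PartitionIntegrityError
        If a node in ``nodes`` has no cluster assignment.
    """
    assignment = getattr(partition, "assignment", partition)
    if nodes is not None:
        missing = sorted(set(nodes) - set(assignment))
        if missing:
            raise PartitionIntegrityError(f"unassigned node(s): {missing[:5]}")
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(assignment):
            fh.write(f"{node}\t{int(assignment[node])}\n")


def read_partition(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV partition file; inverse of :func:`write_partition`.

    Cluster ids need not be contiguous.

    Raises
    ------
    PartitionIntegrityError
        On a duplicate node row.
    GraphFormatError
        On a malformed row.
    """
    assignment: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_COMMENT_PREFIXES):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise GraphFormatError(f"{path}: line {lineno}: expected 2 columns")
            node = parts[0]
            if node in assignment:
                raise PartitionIntegrityError(f"{path}: line {lineno}: duplicate node {node!r}")
            try:
                assignment[node] = int(parts[1])
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}: line {lineno}: cluster id {parts[1]!r} is not an integer"
                ) from exc
    return assignment


@dataclass(frozen=True)
class GraphSummary:
    """Descriptive statistics of a network.

    ``avg_clustering`` is the mean local clustering coefficient over *all*
    nodes, with degree-0/1 nodes contributing 0.  ``diameter`` and
    ``avg_shortest_path`` are hop counts over the largest connected component
    (mean over unordered connected pairs).
    """

    n_nodes: int
    n_edges: int
    n_triangles: int
    avg_clustering: float
    diameter: int
    avg_shortest_path: float

    def to_dict(self) -> dict:
        return asdict(self)


def graph_summary(g: nx.Graph) -> GraphSummary:
    """Compute the six descriptive statistics for a nonempty graph."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph_summary requires a nonempty graph")
    n_triangles = sum(nx.triangles(g).values()) // 3
    avg_clustering = nx.average_clustering(g, count_zeros=True)
    giant = max(nx.connected_components(g), key=len)
    sub = g.subgraph(giant)
    if len(giant) > 1:
        diameter = nx.diameter(sub)
        # mean over unordered connected pairs
        total = 0
        npairs = 0
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            npairs += len(dists) - 1
        avg_path = total / npairs
    else:
        diameter = 0
        avg_path = 0.0
    return GraphSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_triangles=n_triangles,
        avg_clustering=avg_clustering,
        diameter=diameter,
        avg_shortest_path=avg_path,
    )


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write an edge list, one ``u v`` pair per line, sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")
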