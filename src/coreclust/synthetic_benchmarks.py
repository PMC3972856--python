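"""Planted-partition benchmark graphs and partition-recovery scoring.

The planted-partition model draws an edge independently for every intra-block
node pair with probability ``p_in`` and for every inter-block pair with
``p_out`` (p_out < p_in), giving a random graph whose ground-truth block
labels are known.  Recovery is scored with normalized mutual information,

    NMI(A, B) = 2 I(A; B) / (H(A) + H(B)),

which is 1 iff the two partitions agree up to relabeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-partition draw.

    n_blocks equal blocks of block_size nodes each; the seed makes the draw
    reproducible within this package.
    """

    n_blocks: int
    block_size: int
    p_in: float
    p_out: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError(f"n_blocks must be >= 2, got {self.n_blocks}")
        if self.block_size < 2:
            raise ValueError(f"block_size must be >= 2, got {self.block_size}")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError(
                f"require 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )


def planted_partition(spec: PlantedSpec) -> tuple[nx.Graph, dict[str, int]]:
    """Draw a planted-partition graph; returns (graph, ground-truth labels).

    Node labels are zero-padded strings ("v0000", "v0001", ...) so that
    lexicographic and numeric orderings coincide; block i holds nodes
    [i * block_size, (i+1) * block_size).
    """
    raw = nx.planted_partition_graph(
        spec.n_blocks, spec.block_size, spec.p_in, spec.p_out, seed=spec.seed
    )
    g = nx.Graph()
    label = {i: f"v{i:04d}" for i in raw.nodes()}
    g.add_nodes_from(label[i] for i in sorted(raw.nodes()))
    g.add_edges_from((label[u], label[v]) for u, v in raw.edges() if u != v)
    truth = {label[i]: i // spec.block_size for i in raw.nodes()}
    return g, truth


def nmi(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    """Normalized mutual information between two partitions of the same nodes.

    Conventions for degenerate cases: both partitions single-cluster -> 1.0
    (they are identical up to relabeling); exactly one entropy zero -> 0.0.

    Raises
    ------
    ValueError
        If the two partitions cover different node sets.
    """
    if set(a) != set(b):
        raise ValueError("nmi requires identical node sets")
    n = len(a)
    if n == 0:
        raise ValueError("nmi requires a nonempty node set")
    # contingency table
    joint: dict[tuple[int, int], int] = {}
    ca: dict[int, int] = {}
    cb: dict[int, int] = {}
    for node in a:
        la, lb = a[node], b[node]
        joint[(la, lb)] = joint.get((la, lb), 0) + 1
        ca[la] = ca.get(la, 0) + 1
        cb[lb] = cb.get(lb, 0) + 1
    h_a = -sum((c / n) * math.log(c / n) for c in ca.values() if c)
    h_b = -sum((c / n) * math.log(c / n) for c in cb.values() if c)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mi = 0.0
    for (la, lb), c in joint.items():
        p = c / n
        mi += p * math.log(p * n * n / (ca[la] * cb[lb]))
    return 2.0 * mi / (h_a + h_b)
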