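"""Cluster quality scoring: conductance, expansion, NCP profiles, comparison.

For a cluster S with n_S nodes, m_S internal edges and c_S boundary edges
(edges with exactly one endpoint in S):

    conductance(S) = c_S / (2 m_S + c_S)        lower is better
    expansion(S)   = c_S / n_S                  lower is better

The network community profile (NCP) reports, for every cluster size present
in a partition, the best (minimum) score among clusters of that size; two
algorithms are compared per common size and by their means over clusters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx


@dataclass(frozen=True)
class ClusterScore:
    cluster: int
    n_S: int
    m_S: int
    c_S: int
    conductance: float
    expansion: float

    def to_dict(self) -> dict:
        return asdict(self)


def score_cluster(g: nx.Graph, members: Iterable[str], cluster_id: int = 0) -> ClusterScore:
    """Score one cluster.  A cluster with no incident edges at all scores 0/0.

    Raises
    ------
    ValueError
        On an empty member set or members outside the graph.
    """
    mem = set(members)
    if not mem:
        raise ValueError("score_cluster requires a nonempty member set")
    unknown = mem - set(g.nodes())
    if unknown:
        raise ValueError(f"members not in graph: {sorted(unknown)[:5]}")
    m_s = 0
    c_s = 0
    # nx yields each edge with >=1 endpoint in mem exactly once
    for u, v in g.edges(mem):
        if v in mem and u in mem:
            m_s += 1
        else:
            c_s += 1
    denom = 2 * m_s + c_s
    conductance = c_s / denom if denom > 0 else 0.0
    expansion = c_s / len(mem)
    return ClusterScore(
        cluster=cluster_id,
        n_S=len(mem),
        m_S=m_s,
        c_S=c_s,
        conductance=conductance,
        expansion=expansion,
    )


def score_partition(g: nx.Graph, assignment: Mapping[str, int]) -> list[ClusterScore]:
    """Score every cluster of a complete partition, ordered by cluster id."""
    clusters: dict[int, set[str]] = {}
    for node, cid in assignment.items():
        clusters.setdefault(cid, set()).add(node)
    return [score_cluster(g, mem, cluster_id=cid) for cid, mem in sorted(clusters.items())]


def ncp_profile(scores: Sequence[ClusterScore]) -> dict:
    """Per-size best (minimum) conductance/expansion plus means over clusters."""
    by_size: dict[int, tuple[float, float]] = {}
    for s in scores:
        cur = by_size.get(s.n_S)
        if cur is None:
            by_size[s.n_S] = (s.conductance, s.expansion)
        else:
            by_size[s.n_S] = (min(cur[0], s.conductance), min(cur[1], s.expansion))
    n = len(scores)
    return {
        "profile": {size: by_size[size] for size in sorted(by_size)},
        "mean_conductance": sum(s.conductance for s in scores) / n if n else 0.0,
        "mean_expansion": sum(s.expansion for s in scores) / n if n else 0.0,
        "n_clusters": n,
    }


@dataclass(frozen=True)
class ComparisonReport:
    """Head-to-head comparison of two algorithms' cluster scores.

    Win fractions count the common cluster sizes at which A's best score is
    strictly lower (better) than B's; None when there is no common size.
    """

    mean_conductance_a: float
    mean_conductance_b: float
    mean_expansion_a: float
    mean_expansion_b: float
    common_sizes: list[int]
    only_a_sizes: list[int]
    only_b_sizes: list[int]
    conductance_win_fraction_a: float | None
    expansion_win_fraction_a: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def compare(scores_a: Sequence[ClusterScore], scores_b: Sequence[ClusterScore]) -> ComparisonReport:
    """Compare two score lists on the cluster sizes present in both.

    Raises
    ------
    ValueError
        If either score list is empty.
    """
    if not scores_a or not scores_b:
        raise ValueError("compare requires two nonempty score lists")
    prof_a = ncp_profile(scores_a)
    prof_b = ncp_profile(scores_b)
    sizes_a = set(prof_a["profile"])
    sizes_b = set(prof_b["profile"])
    common = sorted(sizes_a & sizes_b)
    if common:
        cond_wins = sum(
            1 for s in common if prof_a["profile"][s][0] < prof_b["profile"][s][0]
        )
        exp_wins = sum(
            1 for s in common if prof_a["profile"][s][1] < prof_b["profile"][s][1]
        )
        cond_frac: float | None = cond_wins / len(common)
        exp_frac: float | None = exp_wins / len(common)
    else:
        cond_frac = exp_frac = None
    return ComparisonReport(
        mean_conductance_a=prof_a["mean_conductance"],
        mean_conductance_b=prof_b["mean_conductance"],
        mean_expansion_a=prof_a["mean_expansion"],
        mean_expansion_b=prof_b["mean_expansion"],
        common_sizes=common,
        only_a_sizes=sorted(sizes_a - sizes_b),
        only_b_sizes=sorted(sizes_b - sizes_a),
        conductance_win_fraction_a=cond_frac,
        expansion_win_fraction_a=exp_frac,
    )
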