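import math

import networkx as nx
import pytest

from coreclust.core_detection import CoreParams
from coreclust.influence_clustering import (
    DeferAssignment,
    Partition,
    assign_contested,
    centralization,
    cluster,
    total_centralization,
)
from coreclust.synthetic_benchmarks import PlantedSpec, nmi, planted_partition

from conftest import as_str, random_graphs


class TestCentralization:
    def test_uniform_profile_is_noncore(self):
        assert centralization([0.3, 0.3, 0.3]) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_one_hot_profile_is_fully_centralized(self, n):
        assert centralization([1.0] + [0.0] * (n - 1)) == pytest.approx(1.0)

    def test_hand_profile(self):
        # gaps to the max 0.6 are (0, 0.2, 0.4): 0.6 / (2 * 0.4)
        assert centralization([0.6, 0.4, 0.2]) == pytest.approx(0.75)

    def test_singleton_is_zero(self):
        assert centralization([0.7]) == 0.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            centralization([])

    @pytest.mark.parametrize(
        "profile", [[0.1, 0.9], [0.5, 0.2, 0.9, 0.9], [0.0, 0.0, 1.0, 0.3]]
    )
    def test_range_and_scale_invariance(self, profile):
        v = centralization(profile)
        assert 0.0 <= v <= 1.0
        assert centralization([3.7 * x for x in profile]) == pytest.approx(v)


class TestTotalCentralization:
    def test_uniform_clusters_sum_to_zero(self):
        part = Partition(assignment={"a": 1, "b": 1, "c": 2, "d": 2})
        ca = {"a": 0.5, "b": 0.5, "c": 0.1, "d": 0.1}
        assert total_centralization(part, ca) == 0.0

    def test_two_one_hot_clusters(self):
        part = Partition(assignment={x: (1 if x < "d" else 2) for x in "abcdef"})
        ca = {"a": 1, "b": 0, "c": 0, "d": 1, "e": 0, "f": 0}
        assert total_centralization(part, ca) == pytest.approx(2.0)

    def test_mixed_profiles(self):
        part = Partition(assignment={"a": 1, "b": 1, "c": 1, "d": 2, "e": 2})
        ca = {"a": 0.6, "b": 0.4, "c": 0.2, "d": 0.5, "e": 0.5}
        assert total_centralization(part, ca) == pytest.approx(0.75)


class TestAssignContested:
    def test_single_candidate(self):
        g = nx.Graph([("u", "a"), ("a", "b")])
        part = Partition(
            assignment={"a": 3, "b": 3}, states={"a": "P", "b": "P", "u": "Q"}
        )
        ca = {"u": 0.0, "a": 1.0, "b": 0.0}
        assert assign_contested("u", part, g, ca) == 3
        assert part.states["u"] == "P"

    def test_edge_tie_break(self):
        # two candidate clusters with identical C_A profiles: objective ties,
        # u has 2 edges into cluster 1 and 1 into cluster 2
        g = nx.Graph([("u", "a1"), ("u", "a2"), ("u", "b1"), ("a1", "a2"), ("b1", "b2")])
        part = Partition(
            assignment={"a1": 1, "a2": 1, "b1": 2, "b2": 2},
            states={"a1": "P", "a2": "P", "b1": "P", "b2": "P", "u": "Q"},
        )
        ca = {x: 0.0 for x in g.nodes()}
        assert assign_contested("u", part, g, ca) == 1

    def test_smaller_id_on_full_tie(self):
        g = nx.Graph([("u", "a1"), ("u", "b1"), ("a1", "a2"), ("b1", "b2")])
        part = Partition(
            assignment={"a1": 5, "a2": 5, "b1": 2, "b2": 2},
            states={"a1": "P", "a2": "P", "b1": "P", "b2": "P", "u": "Q"},
        )
        ca = {x: 0.0 for x in g.nodes()}
        assert assign_contested("u", part, g, ca) == 2

    def test_maximizes_brute_force_objective(self):
        """The chosen cluster matches exhaustive evaluation of the summed
        centralization over both tentative assignments."""
        g = nx.Graph([("u", "a1"), ("u", "b1"), ("a1", "a2"), ("b1", "b2"), ("b1", "b3")])
        ca = {"u": 0.0, "a1": 0.8, "a2": 0.0, "b1": 0.8, "b2": 0.8, "b3": 0.8}
        assignment = {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "b3": 2}

        def brute(target):
            groups = {}
            trial = dict(assignment, u=target)
            for node, cid in trial.items():
                groups.setdefault(cid, []).append(ca[node])
            return sum(centralization(v) for v in groups.values())

        best = max((1, 2), key=lambda cid: (brute(cid), -cid))
        part = Partition(
            assignment=dict(assignment),
            states={**{x: "P" for x in assignment}, "u": "Q"},
        )
        assert assign_contested("u", part, g, ca) == best

    def test_defer_without_clustered_neighbor(self):
        g = nx.Graph([("u", "v")])
        part = Partition(states={"u": "Q", "v": "Q"})
        with pytest.raises(DeferAssignment):
            assign_contested("u", part, g, {"u": 0.0, "v": 0.0})


class TestCluster:
    def test_complete_graph_single_cluster(self):
        g = as_str(nx.complete_graph(5))
        part, report = cluster(g, validate=True)
        assert report["n_clusters"] == 1
        assert len(set(part.assignment.values())) == 1

    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        part, report = cluster(g, validate=True)
        assert report["n_clusters"] == 4
        assert sorted(part.assignment) == list("abcd")

    def test_disjoint_cliques_recovered_exactly(self):
        g, truth = planted_partition(PlantedSpec(4, 25, 1.0, 0.0, seed=7))
        part, report = cluster(g, validate=True)
        assert report["n_clusters"] == 4
        assert nmi(truth, part.assignment) == pytest.approx(1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            cluster(nx.Graph())

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_complete_deterministic_assignment(self, seed):
        g, _ = planted_partition(PlantedSpec(3, 12, 0.5, 0.05, seed=seed))
        part1, rep1 = cluster(g, validate=True)
        part2, rep2 = cluster(g)
        # completeness: every node assigned exactly once, no Q/R left
        assert set(part1.assignment) == set(g.nodes())
        assert all(s == "P" for s in part1.states.values())
        # determinism: identical reruns
        assert part1.assignment == part2.assignment
        assert rep1 == rep2
        # every nonempty cluster id has members and a core
        sizes = rep1["cluster_sizes"]
        assert all(v >= 1 for v in sizes.values())
        assert set(rep1["cores"]) == set(sizes)

    def test_founding_events_bounded_by_candidates(self):
        g, _ = planted_partition(PlantedSpec(3, 12, 0.5, 0.05, seed=4))
        part, report = cluster(g)
        # connected graph: all foundings come from the candidate list
        assert nx.is_connected(g)
        n = g.number_of_nodes()
        assert report["founding_events"] <= math.ceil(0.2 * n)

    def test_cores_keep_their_clusters(self):
        g, _ = planted_partition(PlantedSpec(3, 12, 0.5, 0.05, seed=5))
        part, _ = cluster(g)
        for cid, core in part.cores.items():
            if core in part.assignment:
                assert part.assignment[core] == cid

    @pytest.mark.parametrize("order", ["ca", "betweenness", "degree"])
    def test_order_keys_all_complete(self, order):
        g, _ = planted_partition(PlantedSpec(3, 10, 0.6, 0.05, seed=6))
        part, _ = cluster(g, order=order, validate=True)
        assert set(part.assignment) == set(g.nodes())
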