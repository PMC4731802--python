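"""Contact maps, weighted networks, pathways, communities, CRD."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allopath import network as nm
from allopath import synthetic_data as sd
from allopath.errors import AlignmentError, PartitionError
from allopath.trajectory_io import SiteTrajectory
from conftest import build_net, random_weighted_graph, two_k5_bridge  # noqa: F401


def pair_traj(distance, n_frames=4, every_other=False):
    """Two sites a fixed distance apart (optionally only in half the frames)."""
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, 0] = distance
    if every_other:
        coords[1::2, 1, 0] = distance + 10.0
    return SiteTrajectory(coords=coords, res_ids=np.array([1, 2]),
                          res_names=np.array(["ALA", "GLY"]),
                          chains=np.array(["A", "A"]))


class TestContactMap:
    def test_within_cutoff_every_frame_is_contact(self):
        cm = nm.contact_map(pair_traj(5.0))
        assert cm.fraction[0, 1] == 1.0
        assert cm.adjacency[0, 1]

    def test_beyond_cutoff_is_no_contact(self):
        cm = nm.contact_map(pair_traj(6.0))
        assert cm.fraction[0, 1] == 0.0
        assert not cm.adjacency[0, 1]

    def test_half_frames_below_frame_cutoff(self):
        cm = nm.contact_map(pair_traj(5.0, n_frames=4, every_other=True))
        assert cm.fraction[0, 1] == 0.5
        assert not cm.adjacency[0, 1]  # 0.5 < 0.75

    def test_heavy_atoms_only(self):
        # hydrogens must not create contacts: put an H within cutoff but
        # all heavy atoms outside
        from allopath.trajectory_io import StructureModel, Trajectory
        model = StructureModel(
            atom_names=np.array(["CA", "HA", "CA"]),
            atom_elements=np.array(["C", "H", "C"]),
            atom_resindex=np.array([0, 0, 1]),
            atom_coords=np.zeros((3, 3)),
            atom_is_hydrogen=np.array([False, True, False]),
            res_ids=np.array([1, 2]), res_names=np.array(["ALA", "ALA"]),
            res_chains=np.array(["A", "A"]))
        coords = np.zeros((2, 3, 3))
        coords[:, 1, 0] = 6.0   # hydrogen near residue 2
        coords[:, 2, 0] = 8.0   # heavy atom far
        cm = nm.contact_map(Trajectory(coords=coords), model)
        assert not cm.adjacency[0, 1]


class TestBuildNetwork:
    def _contacts(self, n=2):
        frac = np.ones((n, n))
        np.fill_diagonal(frac, 0.0)
        return nm.ContactMap(fraction=frac, distance_cutoff=5.5,
                             frame_cutoff=0.75)

    def test_edge_length_is_minus_log_gc(self):
        gc = np.array([[1.0, 0.5], [0.5, 1.0]])
        net = nm.build_network(self._contacts(), gc)
        assert net.graph[0][1]["length"] == pytest.approx(0.6931, abs=1e-4)

    def test_gc_one_gives_zero_length(self):
        gc = np.array([[1.0, 1.0], [1.0, 1.0]])
        net = nm.build_network(self._contacts(), gc)
        assert net.graph[0][1]["length"] == 0.0

    def test_gc_zero_contact_dropped_with_warning(self):
        gc = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="dropped"):
            net = nm.build_network(self._contacts(), gc)
        assert net.graph.number_of_edges() == 0

    def test_residue_list_mismatch(self):
        with pytest.raises(AlignmentError):
            nm.build_network(self._contacts(2), np.eye(3))


def brute_force_shortest(net, s, t):
    best_len, best_path = np.inf, None
    for path in nx.all_simple_paths(net.graph, s, t):
        length = sum(net.graph[u][v]["length"] for u, v in zip(path, path[1:]))
        if length < best_len - 1e-12:
            best_len, best_path = length, path
    return best_len, best_path


class TestShortestPaths:
    def test_triangle_hand_solution(self):
        net = build_net([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.0)])
        p = nm.shortest_path(net, "A", "C")
        assert p.nodes == ["A", "B", "C"]
        assert p.length == pytest.approx(2.0)

    def test_single_edge(self):
        net = build_net([(0, 1, 0.3)])
        p = nm.shortest_path(net, 0, 1)
        assert p.nodes == [0, 1]
        assert p.length == pytest.approx(0.3)

    def test_unreachable_is_status_not_exception(self):
        net = build_net([(0, 1, 1.0), (2, 3, 1.0)])
        p = nm.shortest_path(net, 0, 3)
        assert p.classification == "unreachable"
        assert p.length == np.inf

    def test_random_graphs_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            net = random_weighted_graph(rng, int(rng.integers(4, 9)))
            nodes = net.nodes()
            s, t = nodes[0], nodes[-1]
            p = nm.shortest_path(net, s, t)
            blen, _ = brute_force_shortest(net, s, t)
            assert p.length == pytest.approx(blen, abs=1e-9)
            assert p.recompute_length(net) == pytest.approx(p.length, abs=1e-9)


def brute_force_suboptimal(net, s, t, tol):
    paths = []
    for path in nx.all_simple_paths(net.graph, s, t):
        length = sum(net.graph[u][v]["length"] for u, v in zip(path, path[1:]))
        paths.append((length, path))
    best = min(l for l, _ in paths)
    bound = best * (1 + tol) + 1e-12
    return sorted((l, p) for l, p in paths if l <= bound)


class TestSuboptimalPaths:
    def test_two_percent_threshold_arithmetic(self):
        # three parallel 2-hop routes of lengths 10, 10.1, 10.3
        net = build_net([("s", "a", 5.0), ("a", "t", 5.0),
                         ("s", "b", 5.0), ("b", "t", 5.1),
                         ("s", "c", 5.0), ("c", "t", 5.3)])
        res = nm.suboptimal_paths(net, "s", "t", tolerance=0.02)
        lengths = sorted(round(p.length, 6) for p in res)
        assert lengths == [10.0, 10.1]

    def test_unique_topology_returns_only_shortest(self):
        net = build_net([(0, 1, 1.0), (1, 2, 1.0)])
        res = nm.suboptimal_paths(net, 0, 2)
        assert len(res) == 1
        assert res[0].classification == "shortest"

    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            net = random_weighted_graph(rng, 7)
            s, t = 0, 6
            res = nm.suboptimal_paths(net, s, t, tolerance=0.02)
            brute = brute_force_suboptimal(net, s, t, 0.02)
            assert len(res) == len(brute)
            for p, (blen, bpath) in zip(res, brute):
                assert p.length == pytest.approx(blen, abs=1e-9)
            assert {tuple(p.nodes) for p in res} == {tuple(p) for _, p in brute}

    def test_truncation_warns(self):
        net = nm.WeightedNetwork(graph=nx.complete_graph(8))
        for u, v in net.graph.edges:
            net.graph[u][v].update(gc=1.0, weight=1.0, length=1.0)
        with pytest.warns(UserWarning, match="truncated"):
            res = nm.suboptimal_paths(net, 0, 7, tolerance=5.0, max_paths=10)
        assert len(res) == 10

    def test_lengths_invariant_to_log_base(self):
        # uniform weight scaling (ln vs log10) must not change the path set
        rng = np.random.default_rng(13)
        net = random_weighted_graph(rng, 7)
        scaled = nm.WeightedNetwork(graph=net.graph.copy())
        for u, v in scaled.graph.edges:
            scaled.graph[u][v]["length"] = net.graph[u][v]["length"] / np.log(10)
        a = nm.suboptimal_paths(net, 0, 6, tolerance=0.02)
        b = nm.suboptimal_paths(scaled, 0, 6, tolerance=0.02)
        assert [p.nodes for p in a] == [p.nodes for p in b]


def brute_force_edge_betweenness(net):
    """Fractional all-pairs shortest-path counts by path enumeration."""
    vals = {tuple(sorted(e)): 0.0 for e in net.graph.edges}
    nodes = net.nodes()
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = []
            best = np.inf
            for path in nx.all_simple_paths(net.graph, s, t):
                length = sum(net.graph[u][v]["length"]
                             for u, v in zip(path, path[1:]))
                if length < best - 1e-9:
                    best, paths = length, [path]
                elif abs(length - best) <= 1e-9:
                    paths.append(path)
            for path in paths:
                for u, v in zip(path, path[1:]):
                    vals[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return vals


class TestEdgeBetweenness:
    def test_path_graph_hand_count(self):
        net = build_net([("A", "B", 1.0), ("B", "C", 1.0)])
        bt = nm.edge_betweenness(net)
        assert bt[("A", "B")] == pytest.approx(2.0)  # pairs AB and AC
        census = nm.edge_betweenness(net, mode="census")
        assert census[("A", "B")] == 2

    def test_barbell_bridge_is_maximal(self, two_k5_bridge):
        bt = nm.edge_betweenness(two_k5_bridge)
        assert max(bt, key=bt.get) == (0, 5)

    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            net = random_weighted_graph(rng, 8)
            bt = nm.edge_betweenness(net)
            brute = brute_force_edge_betweenness(net)
            for e in brute:
                assert bt[e] == pytest.approx(brute[e], abs=1e-6)


class TestGirvanNewman:
    def test_two_clique_bridge_partition_and_modularity(self, two_k5_bridge):
        part = nm.girvan_newman(two_k5_bridge)
        assert part.n_communities == 2
        assert {part.labels[i] for i in range(5)} != \
               {part.labels[i] for i in range(5, 10)}
        # hand value: Q = 2·(10/21 − (21/42)²) = 0.4524
        assert part.q == pytest.approx(0.4524, abs=1e-4)

    def test_complete_graph_stays_single_community(self):
        K6 = nx.complete_graph(6)
        for u, v in K6.edges:
            K6[u][v].update(gc=1.0, weight=1.0, length=1.0)
        part = nm.girvan_newman(nm.WeightedNetwork(graph=K6))
        assert part.n_communities == 1
        assert part.q == 0.0

    def test_recovers_planted_partition(self):
        spec = sd.PlantedGraphSpec(sizes=(5, 5), p_in=0.9, p_out=0.05, seed=3)
        net = sd.planted_partition_graph(spec)
        part = nm.girvan_newman(net)
        truth = nm.CommunityPartition(labels=net.ground_truth, q=0.0)
        assert nm.crd(part, truth) == 0.0

    def test_never_beats_exhaustive_modularity(self):
        from test_synthetic_data import _exhaustive_best_partition
        rng = np.random.default_rng(15)
        for _ in range(3):
            net = random_weighted_graph(rng, 8)
            part = nm.girvan_newman(net)
            best = _exhaustive_best_partition(net)
            assert part.q <= best.q + 1e-9


class TestModularity:
    def test_single_community_exactly_zero(self, two_k5_bridge):
        nodes = list(two_k5_bridge.graph.nodes)
        part = nm.CommunityPartition(labels={u: 0 for u in nodes}, q=0.0)
        assert nm.modularity(two_k5_bridge, part) == 0.0

    def test_matches_networkx_on_random_partitions(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            net = random_weighted_graph(rng, 8)
            labels = {u: int(rng.integers(0, 3)) for u in net.graph.nodes}
            part = nm.CommunityPartition(labels=labels, q=0.0)
            comms = [{u for u in labels if labels[u] == c}
                     for c in set(labels.values())]
            expected = nx.community.modularity(net.graph, comms, weight="weight")
            assert nm.modularity(net, part) == pytest.approx(expected, abs=1e-12)

    def test_uncovered_node_rejected(self, two_k5_bridge):
        with pytest.raises(PartitionError):
            nm.modularity(two_k5_bridge,
                          nm.CommunityPartition(labels={0: 0}, q=0.0))


def random_partition(rng, n, k=3):
    return nm.CommunityPartition(
        labels={i: int(rng.integers(0, k)) for i in range(n)}, q=0.0)


class TestCRD:
    def test_identical_partitions_zero(self):
        p = nm.CommunityPartition(labels={0: 0, 1: 0, 2: 1}, q=0.0)
        assert nm.crd(p, p) == 0.0

    def test_four_node_example(self):
        # {12|34} vs {13|24}: 4 of 6 pairs disagree
        p1 = nm.CommunityPartition(labels={1: 0, 2: 0, 3: 1, 4: 1}, q=0.0)
        p2 = nm.CommunityPartition(labels={1: 0, 3: 0, 2: 1, 4: 1}, q=0.0)
        assert nm.crd(p1, p2) == pytest.approx(4 / 6)

    def test_symmetric_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            p1, p2 = random_partition(rng, n), random_partition(rng, n)
            assert nm.crd(p1, p2) == nm.crd(p2, p1)
            assert 0.0 <= nm.crd(p1, p2) <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(3, 10), st.integers(0, 10_000))
    def test_pseudometric_triangle_inequality(self, n, seed):
        rng = np.random.default_rng(seed)
        p1, p2, p3 = (random_partition(rng, n) for _ in range(3))
        assert nm.crd(p1, p3) <= nm.crd(p1, p2) + nm.crd(p2, p3) + 1e-12

    def test_node_set_mismatch(self):
        p1 = nm.CommunityPartition(labels={0: 0, 1: 0}, q=0.0)
        p2 = nm.CommunityPartition(labels={0: 0, 2: 0}, q=0.0)
        with pytest.raises(AlignmentError):
            nm.crd(p1, p2)

    def test_ordered_denominator_option(self):
        p1 = nm.CommunityPartition(labels={1: 0, 2: 0, 3: 1, 4: 1}, q=0.0)
        p2 = nm.CommunityPartition(labels={1: 0, 3: 0, 2: 1, 4: 1}, q=0.0)
        assert nm.crd(p1, p2, denominator="ordered") == pytest.approx(8 / 16)


class TestCutoffScan:
    @pytest.fixture(scope="class")
    def toy(self):
        traj, info = sd.toy_two_domain_trajectory(seed=2, n_frames=500)
        gc = sd.analytic_gc_matrix(info["spec"])
        return traj, gc

    def test_identical_grid_points_zero_crd(self, toy):
        traj, gc = toy
        df = nm.cutoff_scan(traj, gc, [5.5, 5.5], [0.75])
        assert df.loc[df.axis == "distance", "crd"].iloc[0] == 0.0

    def test_extreme_cutoff_recorded_missing(self, toy):
        traj, gc = toy
        df = nm.cutoff_scan(traj, gc, [1.0, 5.5], [0.75])
        assert np.isnan(df.loc[df.axis == "distance", "crd"].iloc[0])

    def test_robust_communities_plateau(self, toy):
        traj, gc = toy
        df = nm.cutoff_scan(traj, gc, [5.0, 5.5, 6.0], [0.75])
        dd = df[df.axis == "distance"]
        assert dd["converged"].all()
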