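import math

import networkx as nx
import numpy as np
import pytest

from dimerstate.allosteric import (
    binned_mutual_information,
    build_mi_graph,
    define_site_residues,
    hubscores,
    shortest_pipelines,
    torsion_mutual_information,
)
from dimerstate.allosteric import AllostericPipeline, MINetwork
from dimerstate.errors import ConfigurationError, DimerStateError
from dimerstate.interface import detect_contacts
from dimerstate.synthetic import SyntheticSpec, plant_contact_series
from dimerstate.trajectory import TorsionSeries


def make_series(angles, mask=None, chain="T"):
    angles = np.asarray(angles, float)
    n_res = angles.shape[1]
    if mask is None:
        mask = np.ones((n_res, angles.shape[2]), bool)
    return TorsionSeries(
        residues=[(chain, r + 1, "") for r in range(n_res)],
        angles=angles,
        mask=np.asarray(mask, bool),
        res_names=["SER"] * n_res,
    )


class TestMIEstimator:
    def test_closed_form_discrete_joint(self):
        # printed 3-level joint count table; oracle is the direct sum
        counts = np.array([[2, 1, 0], [0, 3, 1], [1, 0, 2]], float)
        xs, ys = [], []
        for i in range(3):
            for j in range(3):
                xs += [i] * int(counts[i, j])
                ys += [j] * int(counts[i, j])
        n = counts.sum()
        p = counts / n
        px, py = p.sum(axis=1), p.sum(axis=0)
        expected = sum(
            p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
            for i in range(3)
            for j in range(3)
            if p[i, j] > 0
        )
        got = binned_mutual_information(np.array(xs), np.array(ys), bins=3)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_identical_series_gives_log2_bins(self):
        codes = np.tile(np.arange(12), 50)
        assert binned_mutual_information(codes, codes, 12) == pytest.approx(
            math.log2(12), abs=1e-9
        )

    def test_self_mi_equals_binned_entropy(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 8, 400)
        p = np.bincount(codes, minlength=8) / len(codes)
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert binned_mutual_information(codes, codes, 8) == pytest.approx(entropy, abs=1e-12)

    def test_network_symmetric_nonnegative_zero_diagonal(self):
        rng = np.random.default_rng(5)
        series = make_series(rng.uniform(-180, 180, (300, 6, 3)))
        net = torsion_mutual_information(series, n_permutations=5, seed=1)
        assert np.allclose(net.mi, net.mi.T)
        assert (net.mi >= 0).all()
        assert np.allclose(np.diag(net.mi), 0)

    def test_coupled_pair_has_high_mi(self):
        rng = np.random.default_rng(6)
        shared = rng.uniform(-180, 180, 500)
        angles = rng.uniform(-180, 180, (500, 3, 3))
        angles[:, 0, 0] = shared
        angles[:, 1, 0] = shared
        net = torsion_mutual_information(make_series(angles), n_permutations=5, seed=2)
        assert net.mi[0, 1] > 2.0
        assert net.mi[0, 2] < 0.2

    def test_all_masked_residue_dropped(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(-180, 180, (200, 4, 3))
        mask = np.ones((4, 3), bool)
        mask[2] = False
        with pytest.warns(UserWarning):
            net = torsion_mutual_information(make_series(angles, mask), n_permutations=2)
        assert len(net.residues) == 3

    def test_too_few_bins_rejected(self):
        series = make_series(np.zeros((200, 3, 3)))
        with pytest.raises(ConfigurationError):
            torsion_mutual_information(series, bins=4)

    def test_few_frames_warns(self):
        series = make_series(np.zeros((50, 3, 3)))
        with pytest.warns(UserWarning, match="frames"):
            torsion_mutual_information(series, n_permutations=2)


class TestGraph:
    def _network(self, mi, positions, chain="T"):
        n = len(positions)
        residues = [(chain, r + 1, "") for r in range(n)]
        net = MINetwork(residues=residues, mi=np.asarray(mi, float), bins=24,
                        n_permutations=0, seed=0)
        atoms = []
        coords = []
        for r, x in enumerate(positions):
            atoms.append((chain, r + 1))
            coords.append([x, 0.0, 0.0])
        from tests.conftest import build_model

        topo = build_model(
            [(chain, r + 1, "SER", "CA", "C", tuple(c)) for r, c in enumerate(coords)],
            protomer_map={chain: "A"},
        )
        return net, topo

    def test_proximity_eligibility(self):
        mi = [[0, 1.0, 0.8], [1.0, 0, 1.0], [0.8, 1.0, 0]]
        net, topo = self._network(mi, [0.0, 6.0, 12.0])
        g = build_mi_graph(net, topo, proximity_cutoff=10.0)
        assert g.has_edge(("T", 1, ""), ("T", 2, ""))
        assert g.has_edge(("T", 2, ""), ("T", 3, ""))
        assert not g.has_edge(("T", 1, ""), ("T", 3, ""))

    def test_equal_mi_equal_weights(self):
        mi = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
        net, topo = self._network(mi, [0.0, 5.0, 10.0])
        g = build_mi_graph(net, topo, proximity_cutoff=6.0)
        weights = {d["weight"] for _, _, d in g.edges(data=True)}
        assert len(weights) == 1

    def test_weight_order_reverses_mi_order(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            vals = rng.uniform(0.01, 2.0, 3)
            mi = np.zeros((4, 4))
            mi[0, 1] = mi[1, 0] = vals[0]
            mi[1, 2] = mi[2, 1] = vals[1]
            mi[2, 3] = mi[3, 2] = vals[2]
            net, topo = self._network(mi, [0.0, 4.0, 8.0, 12.0])
            g = build_mi_graph(net, topo, proximity_cutoff=5.0)
            edges = [(("T", 1, ""), ("T", 2, "")), (("T", 2, ""), ("T", 3, "")),
                     (("T", 3, ""), ("T", 4, ""))]
            mis = [g.edges[e]["mi"] for e in edges]
            ws = [g.edges[e]["weight"] for e in edges]
            assert np.argsort(mis).tolist() == np.argsort(ws)[::-1].tolist()


class TestSiteResidues:
    def test_always_contacting_residues_found(self):
        spec = SyntheticSpec(n_frames=100, contact_plants=[1.0] * 5, seed=9)
        traj, _ = plant_contact_series(spec)
        site = define_site_residues(traj, "S")
        assert site == {("R", i, "") for i in range(1, 6)}

    def test_exact_threshold_excluded(self):
        spec = SyntheticSpec(n_frames=100, contact_plants=[0.60, 0.61], seed=9)
        traj, _ = plant_contact_series(spec)
        site = define_site_residues(traj, "S", threshold=0.60)
        assert site == {("R", 2, "")}

    def test_matches_brute_force_recount(self):
        spec = SyntheticSpec(n_frames=10, contact_plants=[0.7, 0.3, 1.0], seed=13)
        traj, _ = plant_contact_series(spec)
        group_a = [("R", i) for i in range(1, 4)]
        group_b = [("S", i) for i in range(1, 4)]
        counts = {}
        for frame in traj.iter_frames():
            touched = {r.res_a for r in detect_contacts(frame, group_a, group_b)}
            for res in touched:
                counts[res] = counts.get(res, 0) + 1
        expected = {res for res, c in counts.items() if c / traj.n_frames > 0.6}
        assert define_site_residues(traj, "S") == expected

    def test_absent_chain_errors(self):
        spec = SyntheticSpec(n_frames=100, contact_plants=[0.5], seed=1)
        traj, _ = plant_contact_series(spec)
        with pytest.raises(ConfigurationError):
            define_site_residues(traj, "Z")


def path_graph_with_mi(mi_values):
    from dimerstate.allosteric import mi_path_weight

    g = nx.Graph()
    mi_max = max(mi_values)
    for i, mi in enumerate(mi_values):
        g.add_edge(i, i + 1, mi=mi, weight=mi_path_weight(mi, mi_max))
    return g


class TestPipelines:
    def test_unique_path_on_path_graph(self):
        g = path_graph_with_mi([1.0, 0.5, 0.8])
        pipes = shortest_pipelines(g, [0], [3])
        assert len(pipes) == 1
        assert pipes[0].path == [0, 1, 2, 3]
        assert pipes[0].strength == pytest.approx(2.3)
        assert pipes[0].rank == 1

    def test_competing_routes_match_enumeration(self):
        # 6-node graph with two routes; oracle enumerates all simple paths
        g = nx.Graph()
        edges = [
            (0, 1, 1.0), (1, 2, 0.9), (2, 5, 1.0),
            (0, 3, 0.8), (3, 4, 0.85), (4, 5, 0.9),
            (1, 4, 0.1),
        ]
        from dimerstate.allosteric import mi_path_weight

        mi_max = max(m for _, _, m in edges)
        for u, v, m in edges:
            g.add_edge(u, v, mi=m, weight=mi_path_weight(m, mi_max))
        best = min(
            nx.all_simple_paths(g, 0, 5),
            key=lambda p: sum(g[u][v]["weight"] for u, v in zip(p, p[1:])),
        )
        pipes = shortest_pipelines(g, [0], [5])
        assert pipes[0].path == best

    def test_unreachable_pairs_skipped(self):
        g = path_graph_with_mi([1.0])
        g.add_node(99)
        pipes = shortest_pipelines(g, [0], [1, 99])
        assert len(pipes) == 1

    def test_empty_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            shortest_pipelines(nx.Graph(), [], [1])

    def test_top_n_and_ranking(self):
        g = path_graph_with_mi([1.0, 0.9, 0.8, 0.7])
        pipes = shortest_pipelines(g, [0, 1], [3, 4], top_n=3)
        assert len(pipes) == 3
        assert [p.rank for p in pipes] == [1, 2, 3]
        strengths = [p.strength for p in pipes]
        assert strengths == sorted(strengths, reverse=True)


class TestHubscores:
    def test_star_counts_center(self):
        pipes = [
            AllostericPipeline(path=[leaf, "center", leaf + "x"], source=leaf,
                               target=leaf + "x", strength=1.0)
            for leaf in "abcd"
        ]
        table = hubscores(pipes)
        assert table.counts["center"] == 4
        assert table.top(1)[0][0] == "center"

    def test_disjoint_pipelines_all_one(self):
        pipes = [
            AllostericPipeline(path=[f"{k}1", f"{k}2"], source=f"{k}1", target=f"{k}2",
                               strength=1.0)
            for k in range(3)
        ]
        table = hubscores(pipes)
        assert set(table.counts.values()) == {1}

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(21)
        pipes = []
        for _ in range(10):
            path = list(rng.choice(20, size=rng.integers(2, 6), replace=False))
            pipes.append(AllostericPipeline(path=path, source=path[0], target=path[-1],
                                            strength=1.0))
        table = hubscores(pipes)
        expected = {}
        for p in pipes:
            for res in set(p.path):
                expected[res] = expected.get(res, 0) + 1
        assert table.counts == expected
        assert sum(table.counts.values()) >= len(pipes)

    def test_empty_rejected(self):
        with pytest.raises(DimerStateError):
            hubscores([])


def test_dijkstra_matches_enumeration_on_random_small_graphs():
    rng = np.random.default_rng(33)
    for trial in range(10):
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            mi = float(rng.uniform(0.01, 2.0))
            g.edges[u, v]["mi"] = mi
        if g.number_of_edges() == 0:
            continue
        from dimerstate.allosteric import mi_path_weight

        mi_max = max(d["mi"] for _, _, d in g.edges(data=True))
        for u, v in g.edges:
            g.edges[u, v]["weight"] = mi_path_weight(g.edges[u, v]["mi"], mi_max)
        nodes = list(g.nodes)
        s, t = nodes[0], nodes[-1]
        if not nx.has_path(g, s, t) or s == t:
            continue
        best = min(
            nx.all_simple_paths(g, s, t),
            key=lambda p: sum(g[u][v]["weight"] for u, v in zip(p, p[1:])),
        )
        best_w = sum(g[u][v]["weight"] for u, v in zip(best, best[1:]))
        pipes = shortest_pipelines(g, [s], [t])
        got_w = sum(g[u][v]["weight"] for u, v in zip(pipes[0].path, pipes[0].path[1:]))
        assert got_w == pytest.approx(best_w, abs=1e-9)
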