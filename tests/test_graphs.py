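import networkx as nx
import numpy as np
import pytest

import ergraph as eg
from ergraph.graphs import (Construction, SignalGraph, build_eball_graph,
                            build_erg_graph, build_knn_graph, build_opn,
                            build_recurrence_network, build_visibility_graph,
                            read_edgelist, spectral_summary, write_adjacency_mtx,
                            write_edgelist, write_graphml)
from ergraph.signal_io import QuantizedSignal

from _oracles import union_find_components, visibility_edges_cubic


def qsig(levels, Q):
    return QuantizedSignal(levels=np.array(levels, dtype=float), Q=Q)


class TestErgGraph:
    def test_hand_example_weights_and_counts(self):
        g = build_erg_graph(qsig([0.0, 0.5, 1.0, 0.5, 0.0], 3))
        G = g.graph
        assert set(G.nodes) == {0, 1, 2}
        assert G[0][1]["weight"] == pytest.approx(1.0)
        assert G[0][1]["count"] == 2
        assert G[1][2]["weight"] == pytest.approx(1.0)
        assert G[1][2]["count"] == 2
        assert g.n_self_loops == 0

    def test_self_loop_weight_is_q_minus_1(self):
        g = build_erg_graph(qsig([0.5, 0.5], 3))
        assert g.n_nodes == 1
        assert g.graph[1][1]["weight"] == pytest.approx(2.0)
        assert g.graph[1][1]["count"] == 1

    def test_transition_conservation_and_node_bound(self, rng):
        for _ in range(200):
            Q = int(rng.integers(2, 60))
            n = int(rng.integers(1, 200))
            levels = rng.integers(0, Q, size=n) / (Q - 1)
            g = build_erg_graph(qsig(levels, Q))
            assert g.total_transition_count() == n - 1
            assert g.n_nodes <= Q
            for u, v, d in g.graph.edges(data=True):
                lu, lv = u / (Q - 1), v / (Q - 1)
                assert d["weight"] == pytest.approx(1.0 / (abs(lu - lv) + 1.0 / (Q - 1)))

    def test_determinism(self, rng):
        levels = rng.integers(0, 30, size=100) / 29
        g1 = build_erg_graph(qsig(levels, 30))
        g2 = build_erg_graph(qsig(levels, 30))
        assert nx.utils.graphs_equal(g1.graph, g2.graph)

    def test_unit_step_chain_is_connected(self, rng):
        # consecutive levels never differ by more than one step
        steps = rng.integers(-1, 2, size=80)
        idx = np.clip(np.cumsum(steps) + 10, 0, 20)
        g = build_erg_graph(qsig(idx / 20, 21))
        assert nx.is_connected(g.simple()) or g.n_nodes == 1


class TestVisibilityGraph:
    def test_v_shape(self):
        g = build_visibility_graph(eg.Waveform([1.0, 0.0, 1.0]))
        assert set(map(tuple, map(sorted, g.graph.edges))) == {(0, 1), (1, 2), (0, 2)}

    def test_two_samples(self):
        g = build_visibility_graph(eg.Waveform([0.3, 0.7]))
        assert g.graph.number_of_edges() == 1

    def test_concave_signal_only_adjacent(self):
        # strictly concave: only adjacent pairs see each other
        x = [0.0, 0.9, 1.0, 0.9, 0.0]
        g = build_visibility_graph(eg.Waveform(x))
        expected = visibility_edges_cubic(np.array(x))
        assert set(map(tuple, map(sorted, g.graph.edges))) == expected

    def test_matches_cubic_oracle_on_random_signals(self, rng):
        for _ in range(30):
            x = rng.random(int(rng.integers(2, 25)))
            g = build_visibility_graph(eg.Waveform(x)) if x.size >= 2 else None
            assert set(map(tuple, map(sorted, g.graph.edges))) == visibility_edges_cubic(x)


class TestRecurrenceNetwork:
    def test_single_close_pair(self):
        g = build_recurrence_network(eg.Waveform([0.0, 1.0, 0.05]), eps_r=0.1)
        assert set(map(tuple, map(sorted, g.graph.edges))) == {(0, 2)}

    def test_large_threshold_complete(self):
        g = build_recurrence_network(eg.Waveform([0.0, 0.4, 0.9, 1.0]), eps_r=1.5)
        assert g.n_edges == 6

    def test_tiny_threshold_empty(self):
        g = build_recurrence_network(eg.Waveform([0.0, 0.5, 1.0]), eps_r=1e-9)
        assert g.n_edges == 0


class TestKnnGraph:
    def test_two_clusters_k1(self):
        g = build_knn_graph(eg.Waveform([0.0, 0.1, 0.9, 1.0]), k=1)
        assert set(map(tuple, map(sorted, g.graph.edges))) == {(0, 1), (2, 3)}

    def test_k_equals_n_minus_1_complete(self):
        g = build_knn_graph(eg.Waveform([0.0, 0.3, 0.6, 1.0]), k=3)
        assert g.n_edges == 6

    def test_duplicate_values_deterministic(self, rng):
        x = rng.integers(0, 3, size=20) / 2.0
        g1 = build_knn_graph(eg.Waveform(x), k=3)
        g2 = build_knn_graph(eg.Waveform(x), k=3)
        assert nx.utils.graphs_equal(g1.graph, g2.graph)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            build_knn_graph(eg.Waveform([0.0, 1.0]), k=2)


class TestEballGraph:
    def test_adjacent_only(self):
        g = build_eball_graph(qsig([0.0, 0.5, 1.0], 3), eps_b=0.6)
        assert set(map(tuple, map(sorted, g.graph.edges))) == {(0, 1), (1, 2)}

    def test_large_eps_complete(self):
        g = build_eball_graph(qsig([0.0, 0.5, 1.0], 3), eps_b=1.1)
        assert g.n_edges == 3

    def test_eps_at_level_gap_empty(self):
        g = build_eball_graph(qsig([0.0, 0.5, 1.0], 3), eps_b=0.5)
        assert g.n_edges == 0


class TestOpn:
    def test_monotone_signal_single_pattern(self):
        g = build_opn(eg.Waveform(np.linspace(0, 1, 10)), m=3)
        assert g.n_nodes == 1
        assert g.total_transition_count() == 10 - 3

    def test_alternating_two_patterns(self):
        g = build_opn(eg.Waveform([0.0, 1.0, 0.0, 1.0, 0.0]), m=3)
        assert g.n_nodes == 2
        assert g.n_edges == 1

    def test_pattern_space_bound(self, rng):
        import math

        for _ in range(20):
            n = int(rng.integers(5, 40))
            m = int(rng.integers(2, 5))
            g = build_opn(eg.Waveform(rng.random(n)), m=m)
            assert g.n_nodes <= min(n - m + 1, math.factorial(m))


class TestSpectralSummary:
    def test_path_p3_spectrum(self):
        G = nx.path_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        s = spectral_summary(SignalGraph(graph=G, construction=Construction.ERG_GRAPH))
        assert np.allclose(np.sort(s.eigenvalues), [0.0, 1.0, 3.0])

    def test_k4_density_and_spectrum(self):
        G = nx.complete_graph(4)
        nx.set_edge_attributes(G, 1.0, "weight")
        s = spectral_summary(SignalGraph(graph=G, construction=Construction.ERG_GRAPH))
        assert s.density == pytest.approx(1.0)
        assert np.allclose(np.sort(s.eigenvalues), [0.0, 4.0, 4.0, 4.0])

    def test_disconnected_zero_multiplicity(self):
        G = nx.Graph([(0, 1), (2, 3)])
        nx.set_edge_attributes(G, 1.0, "weight")
        s = spectral_summary(SignalGraph(graph=G, construction=Construction.ERG_GRAPH))
        assert np.sum(np.abs(s.eigenvalues) < 1e-9) == 2
        assert s.n_components == 2

    def test_laplacian_properties_against_component_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 12))
            p = rng.uniform(0.1, 0.9)
            G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
            for u, v in G.edges:
                G[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
            s = spectral_summary(SignalGraph(graph=G, construction=Construction.ERG_GRAPH))
            assert np.allclose(s.laplacian.sum(axis=1), 0.0, atol=1e-9)
            assert s.eigenvalues[0] >= -1e-9
            adj = nx.to_numpy_array(G) > 0
            n_comp = len(set(union_find_components(adj)))
            assert np.sum(s.eigenvalues < 1e-8) == n_comp

    def test_self_loops_excluded_everywhere(self):
        g = build_erg_graph(qsig([0.0, 0.0, 0.5, 1.0], 3))
        s = spectral_summary(g)
        assert np.all(np.diag(s.adjacency) == 0)
        assert s.density == pytest.approx(2 * 2 / (3 * 2))

    def test_count_weight_mode(self):
        g = build_erg_graph(qsig([0.0, 0.5, 0.0, 0.5, 1.0], 3))
        s1 = spectral_summary(g)
        s2 = spectral_summary(g, use_count_weight=True)
        assert s2.adjacency[0, 1] == pytest.approx(3 * s1.adjacency[0, 1])


class TestExport:
    def test_edgelist_round_trip_isomorphic(self, tmp_path):
        g = build_erg_graph(qsig([0.0, 0.5, 1.0, 0.5, 0.5, 0.0], 3))
        path = tmp_path / "g.edges"
        write_edgelist(g, path)
        back = read_edgelist(path)
        assert nx.is_isomorphic(
            g.graph, back.graph,
            edge_match=lambda a, b: a["weight"] == pytest.approx(b["weight"])
            and a["count"] == b["count"])

    def test_graphml_parses_back(self, tmp_path):
        g = build_erg_graph(qsig([0.0, 0.5, 1.0], 3))
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 3
        assert back.number_of_edges() == 2

    def test_mtx_adjacency_parses_back(self, tmp_path):
        import scipy.io

        g = build_erg_graph(qsig([0.0, 0.5, 1.0, 0.5], 3))
        path = tmp_path / "a.mtx"
        write_adjacency_mtx(g, path)
        a = scipy.io.mmread(path).toarray()
        s = spectral_summary(g)
        assert np.allclose(a, s.adjacency)
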