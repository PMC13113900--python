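import networkx as nx
import numpy as np
import pytest

import ergraph as eg
from ergraph.features import (algebraic_connectivity, all_pairs_distances,
                              average_clustering, average_path_length,
                              extract_features, feature_table, graph_diameter,
                              graph_radius, number_of_maximal_cliques,
                              read_feature_table, time_domain_features,
                              total_harmonic_centrality, total_load_centrality,
                              write_feature_table)
from ergraph.graphs import Construction, SignalGraph

import _oracles as orc


def wrap(G):
    for u, v in G.edges:
        G[u][v].setdefault("weight", 1.0)
        G[u][v].setdefault("count", 1)
    return SignalGraph(graph=G, construction=Construction.ERG_GRAPH)


def random_graphs(n_graphs=200, n_max=12, seed=777):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.2, 0.9))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.2, 3.0))
            G[u][v]["count"] = 1
        yield G


class TestOracleEquivalence:
    def test_all_features_match_brute_force(self):
        """Every feature agrees with an independent brute-force oracle on
        200 seeded random graphs (hop distances; exhaustive cliques;
        A^3 triangles; dense eigensolver)."""
        for G in random_graphs():
            adj = nx.to_numpy_array(G, weight=None)
            wts = nx.to_numpy_array(G, weight="weight")
            g = wrap(G)
            fv = extract_features(g)
            assert fv.tlc == pytest.approx(orc.total_betweenness_sum(adj), rel=1e-9, abs=1e-9)
            assert fv.thc == pytest.approx(orc.total_harmonic_sum(adj), rel=1e-9)
            assert fv.gnc == orc.maximal_cliques_exhaustive(adj)
            assert fv.cc == pytest.approx(orc.average_clustering_cube(adj), rel=1e-9, abs=1e-12)
            diam, rad, apl = orc.diameter_radius_apl(adj)
            assert fv.diameter == pytest.approx(diam)
            assert fv.radius == pytest.approx(rad)
            assert fv.apl == pytest.approx(apl, rel=1e-9)
            assert fv.lambda2 == pytest.approx(orc.lambda2_dense(wts), rel=1e-9, abs=1e-9)
            assert fv.density == pytest.approx(orc.density_simple(adj), rel=1e-9)

    def test_distance_matrix_matches_floyd_warshall(self):
        for G in random_graphs(50, seed=101):
            adj = nx.to_numpy_array(G, weight=None)
            _, d = all_pairs_distances(wrap(G))
            assert np.array_equal(d, orc.floyd_warshall(adj))


class TestClosedForms:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_complete_graph(self, n):
        g = wrap(nx.complete_graph(n))
        fv = extract_features(g)
        assert fv.tlc == 0.0
        assert fv.thc == n * (n - 1)
        assert fv.gnc == 1
        assert fv.diameter == (1 if n > 1 else 0)
        assert fv.radius == 1
        assert fv.cc == (1.0 if n >= 3 else 0.0)
        assert fv.apl == 1.0
        assert fv.lambda2 == pytest.approx(n)
        assert fv.density == 1.0

    @pytest.mark.parametrize("n", range(2, 11))
    def test_path_graph(self, n):
        g = wrap(nx.path_graph(n))
        fv = extract_features(g)
        assert fv.gnc == n - 1
        assert fv.diameter == n - 1
        assert fv.radius == n // 2
        assert fv.cc == 0.0
        assert fv.lambda2 == pytest.approx(2 * (1 - np.cos(np.pi / n)))

    @pytest.mark.parametrize("n", range(3, 11))
    def test_cycle_graph(self, n):
        fv = extract_features(wrap(nx.cycle_graph(n)))
        assert fv.diameter == n // 2
        assert fv.radius == n // 2
        assert fv.lambda2 == pytest.approx(2 * (1 - np.cos(2 * np.pi / n)))

    @pytest.mark.parametrize("k", range(2, 10))
    def test_star_graph(self, k):
        fv = extract_features(wrap(nx.star_graph(k)))  # center + k leaves
        assert fv.tlc == k * (k - 1) / 2
        assert fv.apl == pytest.approx((2 * k + k * (k - 1) * 2) / ((k + 1) * k))
        assert fv.diameter == (2 if k >= 2 else 1)
        assert fv.radius == 1

    def test_p3_and_p4_handcomputed(self):
        fv = extract_features(wrap(nx.path_graph(3)))
        assert (fv.tlc, fv.thc, fv.gnc) == (1.0, 5.0, 2)
        assert (fv.diameter, fv.radius, fv.cc) == (2.0, 1.0, 0.0)
        assert fv.apl == pytest.approx(4 / 3)
        assert fv.lambda2 == pytest.approx(1.0)
        assert fv.density == pytest.approx(2 / 3)
        assert total_load_centrality(wrap(nx.path_graph(4))) == 4.0

    def test_c6_p5(self):
        assert graph_diameter(wrap(nx.cycle_graph(6))) == 3
        assert graph_radius(wrap(nx.cycle_graph(6))) == 3
        assert graph_diameter(wrap(nx.path_graph(5))) == 4
        assert graph_radius(wrap(nx.path_graph(5))) == 2


class TestMetricSanity:
    def test_radius_diameter_apl_inequalities(self):
        for G in random_graphs(100, seed=55):
            if not nx.is_connected(G):
                continue
            g = wrap(G)
            diam, rad, apl = graph_diameter(g), graph_radius(g), average_path_length(g)
            assert rad <= diam <= 2 * rad
            assert apl <= diam


class TestDisconnectedPolicy:
    def test_two_isolated_nodes_thc_zero(self):
        G = nx.empty_graph(2)
        assert total_harmonic_centrality(wrap(G)) == 0.0

    def test_giant_component_default_strict_raises(self):
        G = nx.Graph([(0, 1), (1, 2), (3, 4)])
        g = wrap(G)
        assert graph_diameter(g) == 2  # largest component P3
        with pytest.raises(ValueError):
            graph_diameter(g, strict=True)
        with pytest.raises(ValueError):
            extract_features(g, strict=True)

    def test_lambda2_single_node(self):
        assert algebraic_connectivity(wrap(nx.empty_graph(1))) == 0.0


class TestExtraction:
    def test_determinism_bit_exact(self):
        g = wrap(nx.gnp_random_graph(10, 0.4, seed=4))
        a, b = extract_features(g), extract_features(g)
        assert a.as_dict() == b.as_dict()

    def test_scale_shift_invariance_through_pipeline(self, rng):
        x = rng.normal(size=300)
        fa = feature_table([eg.Waveform(x, subject_id="a")], Q=40).iloc[0]
        fb = feature_table([eg.Waveform(5.0 * x - 3.0, subject_id="a")], Q=40).iloc[0]
        for c in eg.GRAPH_FEATURE_NAMES:
            assert fa[c] == fb[c]

    def test_feature_table_round_trip(self, toy_waveforms, tmp_path):
        df = feature_table(toy_waveforms, Q=5, include_td=True)
        path = tmp_path / "feat.csv"
        write_feature_table(df, path)
        back = read_feature_table(path)
        assert np.allclose(back[eg.GRAPH_FEATURE_NAMES].to_numpy(),
                           df[eg.GRAPH_FEATURE_NAMES].to_numpy())
        assert list(back["subject_id"]) == ["S1", "S2"]

    def test_missing_feature_column_rejected(self, toy_waveforms, tmp_path):
        df = feature_table(toy_waveforms, Q=5).drop(columns=["apl"])
        path = tmp_path / "feat.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="apl"):
            read_feature_table(path)


class TestTimeDomain:
    def test_recovers_morphology_on_clean_waveform(self):
        from ergraph.synth import generate_waveform, preset
        from dataclasses import replace

        p = replace(preset("CONTROL_LIKE"), noise_sd=0.0, op_amp=0.0)
        w = generate_waveform(p, np.random.default_rng(0))
        td = time_domain_features(w)
        assert td["td_a_lat_ms"] == pytest.approx(p.a_time, abs=2.0)
        assert td["td_b_lat_ms"] == pytest.approx(p.b_time, abs=2.0)
        assert td["td_b_amp"] > td["td_a_amp"] > 0
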