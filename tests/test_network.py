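"""Network construction, betweenness oracle, degree-preserving null."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trisomap import synthetic_data as sd
from trisomap.network import (
    PPINetwork,
    annotate_regulatory,
    betweenness_hubs,
    build_minppinet,
    degree_preserving_null,
    edges_to_graph,
    fit_powerlaw_tail,
    hub_control_metrics,
    hub_subnetwork,
    load_edges,
    randomized_copy,
    topology_diagnostics,
)


def _edge_frame(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


class TestLoadEdges:
    def test_threshold_inclusive_and_scale_autodetect(self, tmp_path):
        path = tmp_path / "edges.tsv"
        _edge_frame(
            [("a", "b", 0.2), ("a", "c", 0.39), ("b", "c", 0.4), ("c", "d", 0.7), ("d", "e", 0.9)]
        ).to_csv(path, sep="\t", index=False)
        out = load_edges(path, 0.4)
        assert len(out) == 3  # 0.4 kept: the threshold is inclusive
        # the same table on the STRING 0-1000 scale filters identically
        path2 = tmp_path / "edges1000.tsv"
        _edge_frame(
            [("a", "b", 200), ("a", "c", 390), ("b", "c", 400), ("c", "d", 700), ("d", "e", 900)]
        ).to_csv(path2, sep="\t", index=False)
        out2 = load_edges(path2, 0.4)
        assert len(out2) == 3
        assert out2["confidence"].max() <= 1.0

    def test_duplicates_collapse_to_max_confidence(self, tmp_path):
        path = tmp_path / "edges.tsv"
        _edge_frame([("a", "b", 0.5), ("b", "a", 0.8)]).to_csv(path, sep="\t", index=False)
        out = load_edges(path, 0.4)
        assert len(out) == 1
        assert out.iloc[0]["confidence"] == 0.8

    def test_scaled_file_equivalent_to_unit_file(self, tmp_path):
        rows = [("a", "b", 0.45), ("b", "c", 0.62), ("c", "d", 0.81)]
        p1, p2 = tmp_path / "unit.tsv", tmp_path / "string.tsv"
        _edge_frame(rows).to_csv(p1, sep="\t", index=False)
        _edge_frame([(a, b, c * 1000) for a, b, c in rows]).to_csv(p2, sep="\t", index=False)
        a, b = load_edges(p1, 0.4), load_edges(p2, 0.4)
        pd.testing.assert_frame_equal(a, b)

    def test_malformed_score_reported_with_line(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("node_a\tnode_b\tscore\na\tb\t0.5\nc\td\toops\n")
        with pytest.raises(ValueError, match="line 3"):
            load_edges(path)

    def test_empty_after_filter_is_an_error(self, tmp_path):
        path = tmp_path / "edges.tsv"
        _edge_frame([("a", "b", 0.1)]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="no edges"):
            load_edges(path, 0.4)


class TestBuildMinPPINet:
    def test_connected_seed_set_needs_no_connectors(self):
        edges = _edge_frame([("a", "b", 0.9), ("b", "c", 0.9), ("c", "x", 0.9)])
        net = build_minppinet(edges, ["a", "b", "c"])
        assert net.connectors == []
        assert sorted(net.graph.nodes) == ["a", "b", "c"]

    def test_unique_shortest_path_connector(self):
        edges = _edge_frame([("a", "b", 0.9), ("b", "c", 0.9)])
        net = build_minppinet(edges, ["a", "c"])
        assert net.connectors == ["b"]
        assert net.graph.nodes["b"]["role"] == "connector"
        assert net.graph.nodes["a"]["role"] == "seed"

    def test_confidence_tie_break_prefers_stronger_path(self):
        # two length-2 paths between the seeds; the higher-confidence one wins
        edges = _edge_frame(
            [("s1", "weak", 0.5), ("weak", "s2", 0.5), ("s1", "strong", 0.9), ("strong", "s2", 0.9)]
        )
        net = build_minppinet(edges, ["s1", "s2"])
        assert net.connectors == ["strong"]

    def test_missing_and_unreachable_seeds_reported(self):
        edges = _edge_frame([("a", "b", 0.9), ("x", "y", 0.9)])
        net = build_minppinet(edges, ["a", "b", "x", "ghost"])
        assert "ghost" in net.missing_seeds
        assert "x" in net.missing_seeds  # disconnected from the kept component
        assert nx.is_connected(net.graph)

    def test_no_seed_present_is_an_error(self):
        edges = _edge_frame([("a", "b", 0.9)])
        with pytest.raises(ValueError, match="no seed"):
            build_minppinet(edges, ["zz"])

    def test_output_connected_and_connectors_essential(self):
        # every connector's removal must disconnect the net or strand a seed
        G, seeds = sd.simulate_ppi(150, 2, seed=31, seed_clique_size=0)
        rng = np.random.default_rng(32)
        chosen = sorted(
            str(n) for n in rng.choice(sorted(G.nodes), size=12, replace=False)
        )
        net = build_minppinet(G, chosen)
        assert nx.is_connected(net.graph)
        assert set(net.seeds) <= set(net.graph.nodes)
        for connector in net.connectors:
            H = net.graph.copy()
            H.remove_node(connector)
            seeds_left = [s for s in net.seeds if s in H]
            stranded = not all(
                nx.has_path(H, seeds_left[0], s) for s in seeds_left[1:]
            ) if seeds_left else True
            assert (not nx.is_connected(H)) or stranded


class TestRegulatoryOverlay:
    def _net(self):
        edges = _edge_frame([("a", "b", 0.9), ("b", "c", 0.8), ("c", "a", 0.7)])
        return build_minppinet(edges, ["a", "b", "c"])

    def test_empty_table_all_predicted(self):
        net, conflicts = annotate_regulatory(self._net(), None)
        classes = [d["interaction_class"] for _, _, d in net.graph.edges(data=True)]
        assert classes == ["predicted"] * 3
        assert conflicts == []

    def test_precedence_activation_over_complex(self):
        reg = pd.DataFrame(
            [("a", "b", "complex"), ("a", "b", "activation")],
            columns=["source", "target", "interaction_class"],
        )
        net, conflicts = annotate_regulatory(self._net(), reg)
        assert net.graph.edges["a", "b"]["interaction_class"] == "activation"
        assert conflicts and conflicts[0][:2] == ("a", "b")

    def test_class_partition_conserved(self):
        reg = pd.DataFrame(
            [("a", "b", "inhibition"), ("b", "c", "expression"), ("zz", "qq", "activation")],
            columns=["source", "target", "interaction_class"],
        )
        net, _ = annotate_regulatory(self._net(), reg)
        classes = [d["interaction_class"] for _, _, d in net.graph.edges(data=True)]
        assert len(classes) == net.graph.number_of_edges()
        assert sorted(classes) == ["expression", "inhibition", "predicted"]
        assert net.graph.graph["regulatory_skipped"] == 1


def _brute_force_betweenness(G):
    """Exhaustive shortest-path enumeration oracle (normalised), independent
    of the library betweenness implementation."""
    nodes = sorted(G.nodes)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # enumerate all simple paths, keep the shortest ones
        paths = list(nx.all_simple_paths(G, s, t))
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    scale = (n - 1) * (n - 2) / 2.0
    return {v: bc[v] / scale for v in nodes}


class TestBetweenness:
    def test_path_graph_centre(self):
        net = build_minppinet(_edge_frame([("a", "b", 1.0), ("b", "c", 1.0)]), ["a", "b", "c"])
        table = betweenness_hubs(net).set_index("node")
        assert table.loc["b", "betweenness"] == pytest.approx(1.0)
        assert table.loc["a", "betweenness"] == 0.0

    def test_star_graph_centre(self):
        rows = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        net = build_minppinet(_edge_frame(rows), ["hub"] + [f"leaf{i}" for i in range(5)])
        table = betweenness_hubs(net).set_index("node")
        assert table.loc["hub", "betweenness"] == pytest.approx(1.0)
        assert (table.drop("hub")["betweenness"] == 0).all()

    def test_matches_exhaustive_oracle_on_atlas_graphs(self):
        # all connected graphs on up to 6 nodes from the graph atlas
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for G in graph_atlas_g():
            if G.number_of_nodes() < 3 or G.number_of_nodes() > 6:
                continue
            if not nx.is_connected(G):
                continue
            G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
            net = PPINetwork(graph=G, seeds=sorted(G.nodes))
            table = betweenness_hubs(net).set_index("node")
            oracle = _brute_force_betweenness(G)
            for v, expected in oracle.items():
                assert table.loc[v, "betweenness"] == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked > 100

    def test_disconnected_input_rejected(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        net = PPINetwork(graph=G, seeds=["a", "c"])
        with pytest.raises(ValueError, match="build_minppinet"):
            betweenness_hubs(net)


class TestHubSubnetwork:
    def test_star_centre_controls_everything_in_one_step(self):
        rows = [("hub", f"leaf{i}", 1.0) for i in range(6)]
        net = build_minppinet(_edge_frame(rows), ["hub"] + [f"leaf{i}" for i in range(6)])
        pct_nodes, pct_seeds = hub_control_metrics(net, "hub", depth=1)
        assert pct_nodes == 100.0
        assert pct_seeds == 100.0

    def test_path_graph_two_step_closure(self):
        rows = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)]
        net = build_minppinet(_edge_frame(rows), list("abcde"))
        sub = hub_subnetwork(net, "a", depth=2)
        assert sorted(sub.nodes) == ["a", "b", "c"]
        pct_nodes, _ = hub_control_metrics(net, "a")
        assert pct_nodes == pytest.approx(50.0)  # {b, c} of the other 4 nodes

    def test_absent_hub_rejected(self):
        net = build_minppinet(_edge_frame([("a", "b", 1.0)]), ["a", "b"])
        with pytest.raises(ValueError, match="not in network"):
            hub_subnetwork(net, "zz")

    def test_connector_relevance_scores_bridging_connector_highest(self):
        from trisomap.network import connector_relevance

        # two seed clusters joined through connector 'mid'; a pendant
        # connector 'stub' hangs off one cluster via a second seed pair
        rows = [
            ("s1", "s2", 0.9), ("s1", "mid", 0.9), ("mid", "s3", 0.9),
            ("s3", "s4", 0.9), ("s4", "stub", 0.9), ("stub", "s5", 0.9),
        ]
        net = build_minppinet(_edge_frame(rows), ["s1", "s2", "s3", "s4", "s5"])
        scores = connector_relevance(net)
        assert set(scores.index) == set(net.connectors)
        assert ((scores >= 0) & (scores <= 1)).all()
        assert scores.index[0] == "mid"  # the central bridge outranks the stub


class TestDegreePreservingNull:
    def test_replicates_preserve_degree_multiset(self):
        G, _ = sd.simulate_ppi(80, 2, seed=33)
        observed = sorted(d for _, d in G.degree())
        for seed in range(25):
            H = randomized_copy(G, seed=seed)
            assert sorted(d for _, d in H.degree()) == observed
            assert H.number_of_edges() == G.number_of_edges()
            assert not any(u == v for u, v in H.edges)

    def test_conserved_metric_has_p_one(self):
        # total seed degree is invariant when every node is a seed
        G, _ = sd.simulate_ppi(60, 2, seed=34)
        net = PPINetwork(graph=G, seeds=sorted(G.nodes))
        res = degree_preserving_null(net, "seed_internal_edges", n_replicates=200, seed=1)
        assert res.empirical_p == 1.0
        assert res.null_sd == 0.0

    def test_four_cycle_triangles_match_exhaustive_enumeration(self):
        # the 4-cycle's degree sequence (2,2,2,2) admits exactly two simple
        # graphs up to labelling: the 4-cycle (0 triangles) and two disjoint
        # triangles -- impossible on 4 nodes, so every replicate has 0 triangles
        G = nx.cycle_graph(4)
        vals = set()
        for seed in range(20):
            H = randomized_copy(G, seed=seed, strict=False)
            vals.add(sum(nx.triangles(H).values()) // 3)
        assert vals == {0}

    def test_planted_clique_significant(self):
        G, seeds = sd.simulate_ppi(300, 2, seed=35, seed_clique_size=10)
        net = PPINetwork(graph=G, seeds=seeds)
        res = degree_preserving_null(net, "seed_internal_edges", n_replicates=2000, seed=2)
        assert res.observed == 45.0
        assert res.empirical_p <= 0.001
        assert res.null_mean < 10.0  # far below the 45 planted internal edges

    def test_determinism(self):
        G, seeds = sd.simulate_ppi(100, 2, seed=36, seed_clique_size=8)
        net = PPINetwork(graph=G, seeds=seeds)
        a = degree_preserving_null(net, "seed_internal_edges", n_replicates=500, seed=3)
        b = degree_preserving_null(net, "seed_internal_edges", n_replicates=500, seed=3)
        assert a == b

    def test_alternative_metrics_run(self):
        G, seeds = sd.simulate_ppi(40, 2, seed=37, seed_clique_size=5)
        net = PPINetwork(graph=G, seeds=seeds)
        for metric in ("global_clustering", "mean_seed_distance"):
            res = degree_preserving_null(net, metric, n_replicates=20, seed=4)
            assert 0 < res.empirical_p <= 1.0

    def test_rigid_graph_rejected(self):
        G = nx.complete_graph(4)
        net = PPINetwork(graph=G, seeds=[0, 1])
        with pytest.raises(ValueError, match="rigid"):
            degree_preserving_null(net, "seed_internal_edges", n_replicates=10, seed=5)


class TestTopology:
    def test_watts_strogatz_is_small_world(self):
        G = nx.connected_watts_strogatz_graph(100, 6, 0.1, seed=38)
        diag = topology_diagnostics(G, n_null=10, seed=6)
        assert diag.small_world_sigma > 1.0

    def test_preferential_attachment_exponent_range(self):
        G, _ = sd.simulate_ppi(500, 2, seed=39)
        diag = topology_diagnostics(G, n_null=5, seed=7)
        assert 2.0 <= diag.powerlaw_alpha <= 4.0

    def test_complete_graph_flagged_dense(self):
        G = nx.complete_graph(25)
        diag = topology_diagnostics(G, n_null=3, seed=8)
        assert diag.dense_graph
        assert diag.clustering == pytest.approx(1.0)


def test_fit_powerlaw_recovers_exponent_on_zipf_sample():
    rng = np.random.default_rng(40)
    sample = rng.zipf(2.5, size=4000)
    alpha, kmin, _ = fit_powerlaw_tail(sample)
    assert alpha == pytest.approx(2.5, abs=0.35)
    assert kmin >= 1
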