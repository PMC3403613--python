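import networkx as nx
import numpy as np
import pytest

from weakties.detection import (
    build_virtual_network,
    closeness,
    detect_complexes,
    mine_cores,
    select_attachments,
    sweep_beta,
    sweep_tau,
)
from weakties.evaluation import f_measure
from weakties.similarity import SimilarityMatrix, pairwise_similarity
from weakties.synthetic import PlantedModel, planted_network

from conftest import make_barbell


def sim_from_entries(vertices, entries, beta=0.618):
    idx = {v: i for i, v in enumerate(vertices)}
    mat = np.zeros((len(vertices), len(vertices)))
    for (u, v), s in entries.items():
        mat[idx[u], idx[v]] = s
        mat[idx[v], idx[u]] = s
    return SimilarityMatrix(vertices=tuple(vertices), matrix=mat, beta=beta)


class TestBuildVirtualNetwork:
    def test_direct_thresholding(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        sim = sim_from_entries("abc", {("a", "b"): 0.5, ("a", "c"): 0.1, ("b", "c"): 0.4})
        vnet = build_virtual_network(net, sim, tau=0.3)
        assert set(map(frozenset, vnet.graph.edges())) == {frozenset("ab"), frozenset("bc")}
        assert set(vnet.graph.nodes()) == set("abc")

    def test_tau_zero_gives_complete_graph(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        sim = sim_from_entries("abc", {("a", "b"): 0.5})
        vnet = build_virtual_network(net, sim, tau=0.0)
        assert vnet.graph.number_of_edges() == 3
        assert not any(u == v for u, v in vnet.graph.edges())

    def test_tau_above_max_gives_edgeless(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        sim = sim_from_entries("abc", {("a", "b"): 0.5})
        vnet = build_virtual_network(net, sim, tau=1.0)
        assert vnet.graph.number_of_edges() == 0
        assert set(vnet.graph.nodes()) == set("abc")

    def test_index_mismatch_rejected(self):
        net = nx.Graph()
        net.add_nodes_from("abcd")
        sim = sim_from_entries("abc", {})
        with pytest.raises(ValueError):
            build_virtual_network(net, sim, tau=0.1)


class TestMineCores:
    def test_two_shared_triangles(self):
        net = nx.Graph()
        net.add_nodes_from("abcd")
        sim = sim_from_entries(
            "abcd",
            {("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1, ("b", "d"): 1, ("c", "d"): 1},
        )
        vnet = build_virtual_network(net, sim, tau=0.5)
        assert mine_cores(vnet, min_core=3) == [frozenset("abc"), frozenset("bcd")]

    def test_k5_single_core(self):
        net = nx.complete_graph(5)
        sim = sim_from_entries(
            list(range(5)), {(i, j): 1.0 for i in range(5) for j in range(i + 1, 5)}
        )
        vnet = build_virtual_network(net, sim, tau=0.5)
        assert mine_cores(vnet, min_core=3) == [frozenset(range(5))]

    def test_edgeless_virtual_network(self):
        net = nx.Graph()
        net.add_nodes_from("ab")
        vnet = build_virtual_network(net, sim_from_entries("ab", {}), tau=0.5)
        assert mine_cores(vnet) == []

    def test_min_core_lower_bound(self):
        net = nx.Graph()
        net.add_nodes_from("ab")
        vnet = build_virtual_network(net, sim_from_entries("ab", {}), tau=0.5)
        with pytest.raises(ValueError):
            mine_cores(vnet, min_core=1)


class TestCloseness:
    def test_single_member_core_halves_similarity(self):
        sim = sim_from_entries("uv", {("u", "v"): 0.8})
        assert closeness("v", {"u"}, sim) == pytest.approx(0.4)

    def test_u_plus_one_denominator(self):
        sim = sim_from_entries("abv", {("v", "a"): 0.6, ("v", "b"): 0.6})
        assert closeness("v", {"a", "b"}, sim) == pytest.approx(0.4)

    def test_all_zero_similarity(self):
        sim = sim_from_entries("abv", {})
        assert closeness("v", {"a", "b"}, sim) == 0.0

    def test_floor_suppresses_subthreshold_pairs(self):
        sim = sim_from_entries("abv", {("v", "a"): 0.6, ("v", "b"): 0.01})
        assert closeness("v", {"a", "b"}, sim, floor=0.05) == pytest.approx(0.2)

    def test_core_member_rejected(self):
        sim = sim_from_entries("ab", {})
        with pytest.raises(ValueError):
            closeness("a", {"a", "b"}, sim)


class TestSelectAttachments:
    def test_average_closeness_rule_hand_example(self):
        # cl(c)=0.4, cl(d)=0.1167, |U|=2 -> acl ~ 0.1292: only c selected
        net = nx.Graph([("u1", "u2"), ("u1", "c"), ("u2", "d")])
        sim = sim_from_entries(
            ["u1", "u2", "c", "d"],
            {("c", "u1"): 0.6, ("c", "u2"): 0.6, ("d", "u1"): 0.25, ("d", "u2"): 0.1},
        )
        assert select_attachments(net, {"u1", "u2"}, sim) == {"c"}

    def test_empty_candidate_set(self):
        net = nx.Graph([("u1", "u2")])
        sim = sim_from_entries(["u1", "u2"], {("u1", "u2"): 1.0})
        assert select_attachments(net, {"u1", "u2"}, sim) == set()

    def test_single_positive_candidate_always_selected(self):
        net = nx.Graph([("u", "v")])
        sim = sim_from_entries("uv", {("u", "v"): 0.3})
        assert select_attachments(net, {"u"}, sim) == {"v"}

    def test_zero_closeness_candidate_never_selected(self):
        net = nx.Graph([("u", "v")])
        sim = sim_from_entries("uv", {("u", "v"): 0.01})
        assert select_attachments(net, {"u"}, sim, floor=0.05) == set()

    def test_empty_core_rejected(self):
        net = nx.Graph([("u", "v")])
        sim = sim_from_entries("uv", {})
        with pytest.raises(ValueError):
            select_attachments(net, set(), sim)


class TestDetectComplexes:
    def test_planted_complexes_recovered_without_noise(self):
        net, truth = planted_network(PlantedModel(complex_count=5, seed=7))
        predicted = detect_complexes(net)
        assert len(predicted) >= len(truth)
        from weakties.evaluation import neighborhood_affinity

        for rec in truth:
            best = max(neighborhood_affinity(p.members, rec.members) for p in predicted)
            assert best >= 0.5

    def test_edgeless_input_empty_catalog(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        assert len(detect_complexes(net)) == 0

    def test_barbell_cliques_not_merged_above_cross_walk_threshold(self):
        # cross-bridge walk similarity in the K_6 barbell is ~0.062 and the
        # bridge pair scores ~0.143: any tau between separates the cliques
        net = make_barbell(6)
        predicted = detect_complexes(net, tau=0.1)
        cores = sorted(tuple(sorted(c.core)) for c in predicted)
        assert cores == [
            tuple(f"v{i:02d}" for i in range(6)),
            tuple(f"v{i:02d}" for i in range(6, 12)),
        ]
        # each complex may adopt the opposite bridge endpoint as an attachment,
        # but never the opposite clique wholesale
        for rec in predicted:
            assert len(rec.members) <= 7

    def test_output_invariants(self):
        net, _ = planted_network(
            PlantedModel(complex_count=6, bridge_edge_count=4, background_noise_prob=0.01, seed=1)
        )
        predicted = detect_complexes(net)
        sim = pairwise_similarity(net)
        vnet = build_virtual_network(net, sim, tau=0.02)
        for rec in predicted:
            core = rec.core
            assert all(vnet.graph.has_edge(u, v) for u in core for v in core if u != v)
            for a in rec.attachments:
                assert any(net.has_edge(a, u) for u in core)

    def test_isomorphism_equivariance(self):
        net, _ = planted_network(PlantedModel(complex_count=4, seed=5))
        mapping = {v: f"X{hash(v) % 10**6}_{v[::-1]}" for v in net.nodes()}
        relabeled = nx.relabel_nodes(net, mapping)
        original = {frozenset(mapping[m] for m in rec.members) for rec in detect_complexes(net)}
        permuted = {frozenset(rec.members) for rec in detect_complexes(relabeled)}
        assert original == permuted

    def test_deterministic(self):
        net, _ = planted_network(PlantedModel(complex_count=4, background_noise_prob=0.02, seed=9))
        a = [(sorted(r.core), sorted(r.attachments)) for r in detect_complexes(net)]
        b = [(sorted(r.core), sorted(r.attachments)) for r in detect_complexes(net)]
        assert a == b


class TestSweeps:
    def test_tau_monotone_virtual_edges(self):
        net, _ = planted_network(PlantedModel(complex_count=5, bridge_edge_count=3, seed=2))
        table = sweep_tau(net, taus=np.linspace(0, 0.5, 11))
        edges = table["virtual_edges"].to_numpy()
        assert (np.diff(edges) <= 0).all()

    def test_tau_sweep_with_benchmark_reports_quality(self):
        net, truth = planted_network(PlantedModel(complex_count=5, seed=4))
        table = sweep_tau(net, taus=[0.02, 0.2], bench=truth)
        assert {"f_measure", "coverage_rate"} <= set(table.columns)
        p, r, f = f_measure(detect_complexes(net, tau=0.02), truth)
        assert table.loc[0, "f_measure"] == pytest.approx(f)

    def test_beta_sweep_emits_rows(self):
        net, _ = planted_network(PlantedModel(complex_count=4, seed=6))
        table = sweep_beta(net, betas=[0.3, 0.618])
        assert len(table) == 2
        assert {"beta", "virtual_edges", "n_complexes"} <= set(table.columns)
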