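"""Graph encoding, interaction taxonomy and node roles."""

import networkx as nx
import numpy as np
import pytest

import qdnet
from qdnet.network import (
    InteractionNetwork,
    build_network,
    classify_pair,
    classify_roles,
    interaction_label,
    pair_table,
    role_table,
    write_graphml,
)


def _net_from_edges(edges, nodes=None):
    g = nx.DiGraph()
    for v in (nodes or []):
        g.add_node(v, weight=1.0, abundance=1.0)
    for u, v, w in edges:
        sign = 0 if w == 0 else int(np.sign(w))
        g.add_edge(u, v, weight=float(w), sign=sign, strength=abs(float(w)))
    return InteractionNetwork(graph=g)


class TestPairClassification:
    # the full 3x3 sign table and its ecological labels
    TABLE = {
        (1, 1): "mutualism", (-1, -1): "antagonism",
        (1, 0): "commensalism", (0, 1): "commensalism",
        (-1, 0): "amensalism", (0, -1): "amensalism",
        (-1, 1): "parasitism", (1, -1): "altruism",
        (0, 0): "neutral",
    }

    def test_exhaustive_enumeration_covers_exactly_seven_labels(self):
        seen = {}
        for sf in (-1, 0, 1):
            for sr in (-1, 0, 1):
                seen[(sf, sr)] = interaction_label(sf, sr)
        assert seen == self.TABLE
        assert len(set(seen.values())) == 7

    def test_one_sided_promotion_is_commensalism(self):
        net = _net_from_edges([("A", "B", 0.5)], nodes=["A", "B"])
        c = classify_pair(net, "A", "B")
        assert c.label == "commensalism"
        assert "A promotes B" in c.note

    def test_reciprocal_promotion_is_mutualism(self):
        net = _net_from_edges([("A", "B", 0.4), ("B", "A", 0.2)])
        assert classify_pair(net, "A", "B").label == "mutualism"

    def test_swap_symmetry_transposes_parasitism_and_altruism(self):
        net = _net_from_edges([("A", "B", -0.4), ("B", "A", 0.2)])
        assert classify_pair(net, "A", "B").label == "parasitism"
        assert classify_pair(net, "B", "A").label == "altruism"

    def test_missing_edges_are_neutral(self):
        net = _net_from_edges([], nodes=["A", "B"])
        assert classify_pair(net, "A", "B").label == "neutral"

    def test_self_pair_rejected(self):
        net = _net_from_edges([], nodes=["A"])
        with pytest.raises(ValueError):
            classify_pair(net, "A", "A")


class TestRoles:
    def test_more_active_than_passive_links_makes_a_leader(self):
        net = _net_from_edges([("A", "B", 1), ("A", "C", 1), ("A", "D", 1),
                               ("B", "A", 1)], nodes=list("ABCD"))
        roles = {r.taxon: r for r in classify_roles(net)}
        assert roles["A"].leader
        assert not roles["B"].leader

    def test_star_center_is_leader_and_hub_leaves_solitary(self):
        center_edges = [("hub", leaf, 1.0) for leaf in "abcde"]
        net = _net_from_edges(center_edges, nodes=["hub", *"abcde"])
        roles = {r.taxon: r for r in classify_roles(net)}
        # mean connectivity = 2*5/6; hub has out=5 > mean; leaves have 1 < mean
        assert roles["hub"].leader and roles["hub"].hub
        for leaf in "abcde":
            assert roles[leaf].solitary

    def test_edgeless_network_has_only_ordinary_nodes(self):
        net = _net_from_edges([], nodes=list("xyz"))
        for r in classify_roles(net):
            assert r.ordinary and not (r.leader or r.hub or r.solitary)

    def test_neutral_edges_do_not_count_toward_degrees(self):
        net = _net_from_edges([("A", "B", 0.0), ("B", "C", 1.0)], nodes=list("ABC"))
        roles = {r.taxon: r for r in classify_roles(net)}
        assert roles["A"].out_degree == 0
        assert roles["B"].out_degree == 1

    def test_roles_invariant_under_uniform_weight_rescaling(self, planted):
        matrix, _ = planted
        qfits = qdnet.fit_qdode(matrix, links=qdnet.select_links(matrix, order=2),
                                order=2)
        net1 = build_network(qfits, eps_factor=0.05)
        # rescale every dependent level by 10 and epsilon identically
        for f in qfits.values():
            for p in f.dependent_level:
                f.dependent_level[p] = 10.0 * f.dependent_level[p]
        net2 = build_network(qfits, epsilon=None, eps_factor=0.05 * 10)
        r1 = {(r.taxon, r.leader, r.hub, r.solitary) for r in classify_roles(net1)}
        r2 = {(r.taxon, r.leader, r.hub, r.solitary) for r in classify_roles(net2)}
        assert r1 == r2


@pytest.fixture(scope="module")
def qfits():
    cfg = qdnet.GeneratorConfig(n_samples=40, n_taxa=8, seed=11, n_partners=2,
                                sigma_log=0.02)
    matrix, _ = qdnet.generate(cfg)
    links = qdnet.select_links(matrix, order=2)
    return matrix, qdnet.fit_qdode(matrix, links=links, order=2)


class TestBuildNetwork:
    def test_single_sample_subset_gives_personalized_network(self, qfits):
        matrix, fits = qfits
        net = build_network(fits, sample_subset=[matrix.sample_ids[3]],
                            scope=matrix.sample_ids[3])
        assert net.scope == matrix.sample_ids[3]
        assert set(net.nodes) >= set(fits)

    def test_edge_support_identical_across_evaluation_subsets(self, qfits):
        matrix, fits = qfits
        full = build_network(fits)
        half = build_network(fits, sample_subset=matrix.sample_ids[:20])
        assert set(full.graph.edges) == set(half.graph.edges)

    def test_no_dependencies_means_edgeless(self, qfits):
        matrix, _ = qfits
        isolated = qdnet.fit_qdode(matrix, links=None, order=2)
        net = build_network(isolated)
        assert net.graph.number_of_edges() == 0

    def test_empty_subset_rejected(self, qfits):
        _, fits = qfits
        with pytest.raises(ValueError):
            build_network(fits, sample_subset=["nope"])

    def test_tables_and_graphml_round_trip(self, qfits, tmp_path):
        _, fits = qfits
        net = build_network(fits)
        edges = net.edge_table()
        assert set(edges.columns) == {"source", "target", "weight", "sign", "strength"}
        assert len(role_table(net)) == len(net.nodes)
        n = len(net.nodes)
        assert len(pair_table(net)) == n * (n - 1) // 2
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        loaded = nx.read_graphml(path)
        assert loaded.number_of_edges() == net.graph.number_of_edges()


class TestMultilayer:
    def test_two_layer_assembly_on_module_structured_data(self):
        cfg = qdnet.GeneratorConfig(n_samples=30, n_taxa=12, n_modules=3, seed=6,
                                    n_partners=2, sigma_bio=0.12, sigma_log=0.05,
                                    module_alpha_jitter=0.0, module_beta_jitter=0.0)
        matrix, _ = qdnet.generate(cfg)
        assignment = qdnet.functional_cluster(matrix, L=3, seed=6)
        ml = qdnet.build_multilayer(matrix, assignment, order=2)
        assert len(ml.coarse.nodes) == 3
        assert set(ml.fine) == {"M1", "M2", "M3"}
        for label, net in ml.fine.items():
            members = assignment.members(int(label[1:]) - 1)
            assert set(net.nodes) == set(members)
            max_edges = len(members) * (len(members) - 1)
            assert net.graph.number_of_edges() <= max_edges


def test_terminal_edge_aggregation_uses_largest_habitat_value(qfits):
    _, fits = qfits
    net = build_network(fits, agg="terminal")
    for u, v, d in net.graph.edges(data=True):
        assert d["weight"] == pytest.approx(float(fits[v].dependent_level[u][-1]))
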