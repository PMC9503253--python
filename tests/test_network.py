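import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cernanet.errors import ValidationError
from cernanet.matrix import ExpressionMatrix
from cernanet.network import (
    CeRNATriple,
    assemble_triples,
    build_network,
    export_network,
    extract_subnetwork,
    hub_nodes,
    node_degrees,
    read_edge_list,
    select_hubs,
)


def brute_force_degrees(net):
    deg = {n: 0 for n in net.graph.nodes}
    for a, b in net.graph.edges:
        deg[a] += 1
        deg[b] += 1
    return deg


class TestBuildNetwork:
    def test_reference_subnetwork_census(self, reference_triples):
        net = build_network(reference_triples)
        census = net.census()
        assert census["n_lncrna"] == 2
        assert census["n_mirna"] == 3
        assert census["n_mrna"] == 12

    def test_empty_triples_empty_graph(self):
        net = build_network([])
        assert net.graph.number_of_nodes() == 0
        assert net.census()["n_edges"] == 0

    def test_duplicate_triples_idempotent(self, reference_triples):
        once = build_network(reference_triples)
        twice = build_network(list(reference_triples) * 2)
        assert set(once.graph.edges) == set(twice.graph.edges)
        assert len(once.triples) == len(twice.triples)

    def test_tripartite_edges_only(self, reference_triples):
        net = build_network(reference_triples)
        for a, b in net.graph.edges:
            ca = net.graph.nodes[a]["feature_class"]
            cb = net.graph.nodes[b]["feature_class"]
            assert {ca, cb} in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"})


class TestDegrees:
    def test_reference_mirna_degree_hand_count(self, reference_triples):
        net = build_network(reference_triples)
        deg = node_degrees(net).set_index("node")["degree"]
        # hsa-miR-103a-3p: 2 lncRNA sponges + 10 distinct mRNA targets
        assert deg["hsa-miR-103a-3p"] == 12
        assert deg["hsa-miR-146b-5p"] == 3  # 2 lncRNAs + SRF
        assert deg["hsa-miR-122-5p"] == 2  # RP11-66N24.4 + NUDT19

    def test_matches_brute_force_incidence(self, reference_triples, recovery_results):
        for net in (build_network(reference_triples), recovery_results.network):
            table = node_degrees(net).set_index("node")["degree"].to_dict()
            assert table == brute_force_degrees(net)

    @given(st.integers(0, 2**31 - 1))
    def test_random_small_networks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        triples = [
            CeRNATriple(
                f"L{rng.integers(4)}", f"M{rng.integers(3)}", f"G{rng.integers(6)}"
            )
            for _ in range(rng.integers(1, 12))
        ]
        net = build_network(triples)
        assert net.graph.number_of_nodes() <= 30
        table = node_degrees(net).set_index("node")["degree"].to_dict()
        assert table == brute_force_degrees(net)


class TestHubs:
    def degree_table(self, degrees):
        return pd.DataFrame(
            {
                "node": [f"N{i}" for i in range(len(degrees))],
                "feature_class": "mRNA",
                "degree": degrees,
            }
        )

    def test_top_decile_with_tie_expansion_on_33_nodes(self):
        # degree profile 26, 5, 3, 2, 2 with 28 further nodes of degree <= 1:
        # k = ceil(0.1 * 33) = 4, and tie expansion at the 4th degree (2)
        # pulls in the fifth node
        degrees = [26, 5, 3, 2, 2] + [1] * 20 + [0] * 8
        ranking = select_hubs(self.degree_table(degrees), 0.10, include_ties=True)
        assert sorted(ranking.selected) == ["N0", "N1", "N2", "N3", "N4"]

    def test_without_ties_strict_ceil_cut(self):
        degrees = [26, 5, 3, 2, 2] + [1] * 28
        ranking = select_hubs(self.degree_table(degrees), 0.10, include_ties=False)
        assert len(ranking.selected) == 4

    def test_all_tied_selects_everyone(self):
        ranking = select_hubs(self.degree_table([3] * 10), 0.1, include_ties=True)
        assert len(ranking.selected) == 10

    def test_fraction_one_selects_all(self):
        ranking = select_hubs(self.degree_table([5, 4, 1]), 1.0)
        assert len(ranking.selected) == 3

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValidationError, match="fraction"):
            select_hubs(self.degree_table([1, 2]), fraction)

    def test_selected_degrees_dominate_unselected(self, recovery_results):
        ranking = hub_nodes(recovery_results.network, 0.10, include_ties=True)
        deg = node_degrees(recovery_results.network).set_index("node")["degree"]
        sel = set(ranking.selected)
        if sel and len(sel) < len(deg):
            assert min(deg[list(sel)]) >= max(deg[deg.index.difference(sel)])


class TestAssemble:
    samples = [f"S{i}" for i in range(8)]

    def mat(self, rows, ids, fclass):
        df = pd.DataFrame(rows, index=ids, columns=self.samples)
        return ExpressionMatrix(df, fclass, "intensity", is_log2=True)

    def base_inputs(self, mir_profile):
        rng = np.random.default_rng(0)
        x = rng.normal(8, 1, size=8)
        lnc = self.mat([x], ["L1"], "lncRNA")
        mrna = self.mat([x + rng.normal(0, 0.05, 8)], ["G1"], "mRNA")
        mir = self.mat([mir_profile(x, rng)], ["M1"], "miRNA")
        coexp = pd.DataFrame(
            {"lncrna_id": ["L1"], "mrna_id": ["G1"], "r": [0.99], "p": [1e-6],
             "n_samples": [8]}
        )
        lm = pd.DataFrame({"source_id": ["L1"], "target_id": ["M1"], "dbs": ["d"]})
        mm = pd.DataFrame({"source_id": ["M1"], "target_id": ["G1"], "dbs": ["d"]})
        return coexp, lm, mm, lnc, mir, mrna

    def test_negatively_correlated_mirna_yields_triple(self):
        coexp, lm, mm, lnc, mir, mrna = self.base_inputs(
            lambda x, rng: -x + rng.normal(0, 0.05, 8) + 20
        )
        triples = assemble_triples(coexp, lm, mm, lnc, mir, mrna)
        assert len(triples) == 1
        t = triples[0]
        assert t.ids == ("L1", "M1", "G1")
        assert t.r_mir_lnc < 0 and t.r_mir_mrna < 0 and t.r_lnc_mrna > 0.9

    def test_positively_correlated_mirna_rejected(self):
        coexp, lm, mm, lnc, mir, mrna = self.base_inputs(
            lambda x, rng: 0.5 * x + rng.normal(0, 0.5, 8)
        )
        assert assemble_triples(coexp, lm, mm, lnc, mir, mrna) == []

    def test_no_shared_mirna_no_triple(self):
        coexp, lm, mm, lnc, mir, mrna = self.base_inputs(
            lambda x, rng: -x + 20
        )
        mm_other = pd.DataFrame(
            {"source_id": ["M2"], "target_id": ["G1"], "dbs": ["d"]}
        )
        assert assemble_triples(coexp, lm, mm_other, lnc, mir, mrna) == []

    def test_missing_expression_named_in_error(self):
        coexp, lm, mm, lnc, mir, mrna = self.base_inputs(lambda x, rng: -x + 20)
        lm_bad = pd.DataFrame({"source_id": ["L1"], "target_id": ["MX"], "dbs": ["d"]})
        mm_bad = pd.DataFrame({"source_id": ["MX"], "target_id": ["G1"], "dbs": ["d"]})
        with pytest.raises(ValidationError, match="MX"):
            assemble_triples(coexp, lm_bad, mm_bad, lnc, mir, mrna)


class TestSubnetwork:
    def test_closure_keeps_whole_triples(self, reference_triples):
        net = build_network(reference_triples)
        hubs = ["hsa-miR-103a-3p", "hsa-miR-146b-5p", "hsa-miR-122-5p",
                "RP11-66N24.4", "LINC00310"]
        sub = extract_subnetwork(net, hubs)
        census = sub.census()
        assert (census["n_lncrna"], census["n_mirna"], census["n_mrna"]) == (2, 3, 12)

    def test_empty_hubs_empty_network(self, reference_triples):
        net = build_network(reference_triples)
        assert extract_subnetwork(net, []).graph.number_of_nodes() == 0

    def test_all_nodes_is_identity(self, reference_triples):
        net = build_network(reference_triples)
        sub = extract_subnetwork(net, list(net.graph.nodes))
        assert set(sub.graph.edges) == set(net.graph.edges)

    def test_unknown_hub_rejected(self, reference_triples):
        net = build_network(reference_triples)
        with pytest.raises(ValidationError, match="NOPE"):
            extract_subnetwork(net, ["NOPE"])

    def test_subnetwork_contained_in_network(self, recovery_results):
        net, sub = recovery_results.network, recovery_results.subnetwork
        assert set(sub.graph.nodes) <= set(net.graph.nodes)
        assert set(map(frozenset, sub.graph.edges)) <= set(
            map(frozenset, net.graph.edges)
        )
        assert set(recovery_results.hubs) <= set(sub.graph.nodes)


class TestExport:
    def test_round_trip_byte_stable(self, reference_triples, tmp_path):
        net = build_network(reference_triples)
        paths = export_network(net, tmp_path / "a")
        g = read_edge_list(paths["edges"])
        net2 = build_network([])  # rebuild container around the parsed graph
        net2.graph = g
        paths2 = export_network(net2, tmp_path / "b")
        assert paths["edges"].read_bytes() == paths2["edges"].read_bytes()

    def test_empty_graph_headers_only(self, tmp_path):
        paths = export_network(build_network([]), tmp_path)
        assert paths["edges"].read_text().strip() == "node_a\tnode_b\tclass_a\tclass_b"

    def test_graphml_is_valid_xml_and_round_trips(self, reference_triples, tmp_path):
        import networkx as nx
        from lxml import etree

        net = build_network(reference_triples)
        paths = export_network(net, tmp_path)
        tree = etree.parse(str(paths["graphml"]))
        assert tree.getroot().tag.endswith("graphml")
        g = nx.read_graphml(paths["graphml"])
        assert set(g.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in g.edges} == {
            frozenset(e) for e in net.graph.edges
        }
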