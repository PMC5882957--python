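"""Tissue assignment, sub-networks, bridging genes, core network, exports."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from estronet import (
    assign_tissue,
    build_core_network,
    export_graph,
    extract_tissue_subnetworks,
    find_bridging_genes,
    import_graph,
    network_summary,
    partition_network,
)
from estronet.expression_io import ProfileMatrix, condition_label
from estronet.topology import TissueAssignment


TISSUES = ("endometrium", "ovary", "oviduct")
DAYS = (0, 3, 6)


def profiles_from(rows: dict[str, list[float]]) -> ProfileMatrix:
    cols = [condition_label(t, d) for t in TISSUES for d in DAYS if d != 0]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "gene"
    return ProfileMatrix(df, TISSUES, DAYS)


def assignment_of(labels: dict[str, str]) -> TissueAssignment:
    table = pd.DataFrame(
        {
            "tissue": pd.Series(labels),
            "max_abs_log2fc": 4.0,
            "peak_day": 3,
            "tied": False,
        }
    )
    table.index.name = "gene"
    return TissueAssignment(table, TISSUES)


class TestAssignTissue:
    def test_peak_condition(self):
        prof = profiles_from({"g0": [0, 1, -4.2, 0, 0, 2]})
        a = assign_tissue(prof)
        assert a.table.loc["g0", "tissue"] == "ovary"
        assert a.table.loc["g0", "peak_day"] == 3
        assert a.table.loc["g0", "max_abs_log2fc"] == pytest.approx(4.2)

    def test_tie_breaks_to_declared_tissue_order_then_day(self):
        prof = profiles_from({"g0": [0, 3.0, 3.0, 0, 0, 0], "g1": [0, 0, 0, 3.0, 3.0, 0]})
        a = assign_tissue(prof)
        assert a.table.loc["g0", "tissue"] == "endometrium"
        assert bool(a.table.loc["g0", "tied"])
        assert a.table.loc["g1", "tissue"] == "ovary"
        assert a.table.loc["g1", "peak_day"] == 6  # ovary:6 precedes oviduct:3

    def test_all_zero_profile_unassigned(self):
        prof = profiles_from({"g0": [0] * 6})
        a = assign_tissue(prof)
        assert a.table.loc["g0", "tissue"] == "unassigned"
        assert a.unassigned == {"g0"}

    def test_synthetic_assignment_matches_planted_tissue(self, noisefree_dataset):
        from estronet import log2fc_profiles

        expr, _, truth = noisefree_dataset
        prof = log2fc_profiles(expr)
        structured = sorted(truth.structured_genes)
        a = assign_tissue(
            ProfileMatrix(prof.data.loc[structured], prof.tissues, prof.days)
        )
        expected = truth.primary_tissue()
        got = a.table.loc[structured, "tissue"]
        assert (got == expected.loc[structured]).all()


class TestSubnetworks:
    def test_triangle_within_one_tissue(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        part = extract_tissue_subnetworks(
            net, assignment_of({"a": "ovary", "b": "ovary", "c": "ovary"})
        )
        sub = part.subnetworks["ovary"]
        assert set(sub.nodes) == {"a", "b", "c"}
        assert sub.number_of_edges() == 3
        assert part.subnetworks["endometrium"].number_of_nodes() == 0

    def test_node_without_intra_tissue_edge_excluded(self):
        net = nx.Graph([("o1", "e1"), ("e1", "e2")])
        part = extract_tissue_subnetworks(
            net, assignment_of({"o1": "ovary", "e1": "endometrium", "e2": "endometrium"})
        )
        assert part.excluded["ovary"] == ["o1"]
        assert set(part.subnetworks["endometrium"].nodes) == {"e1", "e2"}

    def test_unassigned_nodes_reported(self):
        net = nx.Graph([("a", "b")])
        part = extract_tissue_subnetworks(
            net, assignment_of({"a": "ovary", "b": "unassigned"})
        )
        assert part.unassigned == ["b"]

    def test_missing_assignment_errors(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="b"):
            extract_tissue_subnetworks(net, assignment_of({"a": "ovary"}))


class TestBridging:
    def test_path_through_three_tissues(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        labels = assignment_of({"a": "endometrium", "b": "ovary", "c": "oviduct"})
        assert find_bridging_genes(net, labels) == {"b"}

    def test_single_tissue_network_has_none(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        labels = assignment_of({g: "ovary" for g in "abc"})
        assert find_bridging_genes(net, labels) == set()

    def test_own_label_irrelevant(self):
        # d's neighbours span two tissues even though d is one of them
        net = nx.Graph([("d", "e"), ("d", "o")])
        labels = assignment_of({"d": "ovary", "e": "endometrium", "o": "ovary"})
        assert find_bridging_genes(net, labels) == {"d"}

    def test_core_network_and_connectivity(self):
        net = nx.Graph([("b1", "b2"), ("b1", "x"), ("b2", "y"), ("x", "y")])
        core, connectivity = build_core_network(net, {"b1", "b2"})
        assert set(core.nodes) == {"b1", "b2"}
        assert core.number_of_edges() == 1
        assert connectivity == 3  # b1-b2, b1-x, b2-y
        assert connectivity >= core.number_of_edges()

    def test_isolated_bridging_gene(self):
        net = nx.Graph()
        net.add_edges_from(("hub", f"n{i}") for i in range(7))
        core, connectivity = build_core_network(net, {"hub"})
        assert core.number_of_nodes() == 1 and core.number_of_edges() == 0
        assert connectivity == 7

    def test_unknown_bridging_gene_errors(self):
        with pytest.raises(ValueError, match="zz"):
            build_core_network(nx.Graph([("a", "b")]), {"zz"})


class TestNetworkSummary:
    def test_empty_graph(self):
        s = network_summary(nx.Graph())
        assert s == {
            "n_nodes": 0,
            "n_edges": 0,
            "degree_min": 0,
            "degree_median": 0.0,
            "degree_max": 0,
            "n_components": 0,
        }

    def test_triangle(self):
        s = network_summary(nx.complete_graph(3))
        assert (s["n_nodes"], s["n_edges"]) == (3, 3)
        assert s["degree_min"] == s["degree_max"] == 2
        assert s["n_components"] == 1

    def test_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        h = nx.relabel_nodes(g, {n: f"node_{n}" for n in g})
        assert network_summary(g) == network_summary(h)


class TestExportImport:
    def make_graph(self):
        g = nx.Graph()
        g.add_node("a", tissue="ovary", max_abs_log2fc=4.0, bridging=False)
        g.add_node("b", tissue="endometrium", max_abs_log2fc=3.2, bridging=True)
        g.add_node("iso", tissue="oviduct", max_abs_log2fc=3.0, bridging=False)
        g.add_edge("a", "b", r=0.93)
        return g

    def test_graphml_round_trip(self, tmp_path):
        g = self.make_graph()
        path = tmp_path / "g.graphml"
        export_graph(g, "graphml", path)
        back = import_graph(path)
        assert set(back.nodes) == set(g.nodes)
        assert set(back.edges) == set(g.edges)
        assert back.nodes["b"]["tissue"] == "endometrium"
        assert back.nodes["b"]["bridging"] is True
        assert back.edges["a", "b"]["r"] == pytest.approx(0.93)

    def test_sif_single_edge_line(self, tmp_path):
        g = nx.Graph([("x", "y")])
        path = tmp_path / "g.sif"
        export_graph(g, "sif", path)
        lines = path.read_text().strip().split("\n")
        assert lines == ["x\tco\ty"]
        assert set(import_graph(path).edges) == {("x", "y")}

    def test_sif_isolated_nodes(self, tmp_path):
        g = self.make_graph()
        path = tmp_path / "g.sif"
        export_graph(g, "sif", path)
        back = import_graph(path)
        assert set(back.nodes) == {"a", "b", "iso"}

    def test_empty_graph_round_trip(self, tmp_path):
        for fmt in ("graphml", "sif"):
            path = tmp_path / f"empty.{fmt}"
            export_graph(nx.Graph(), fmt, path)
            back = import_graph(path)
            assert back.number_of_nodes() == 0

    def test_attribute_tables(self, tmp_path):
        g = self.make_graph()
        export_graph(
            g,
            "sif",
            tmp_path / "g.sif",
            node_attr_path=tmp_path / "nodes.tsv",
            edge_attr_path=tmp_path / "edges.tsv",
        )
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t").set_index("gene")
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert nodes.loc["a", "tissue"] == "ovary"
        assert len(edges) == 1 and edges.loc[0, "r"] == pytest.approx(0.93)

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError, match="xml"):
            export_graph(nx.Graph(), "xml", tmp_path / "g.xml")

    def test_randomized_round_trips(self, tmp_path):
        """GraphML round-trips random attributed graphs exactly."""
        rng = np.random.default_rng(9)
        for i in range(10):
            g = nx.gnp_random_graph(int(rng.integers(2, 15)), 0.4, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {n: f"gene{n}" for n in g})
            for n in g.nodes:
                g.nodes[n]["tissue"] = str(rng.choice(TISSUES))
                g.nodes[n]["max_abs_log2fc"] = float(rng.uniform(3, 8))
            for u, v in g.edges:
                g.edges[u, v]["r"] = float(rng.uniform(-1, 1))
            path = tmp_path / f"g{i}.graphml"
            export_graph(g, "graphml", path)
            back = import_graph(path)
            assert nx.utils.graphs_equal(back, g)


class TestPartitionNetwork:
    def test_noisefree_partition_matches_truth(self, noisefree_dataset):
        """Full noise-free partition at small scale: tissue sub-network
        node sets equal the planted primary-tissue gene sets, bridging
        detection is exact, and tissues touch only via bridging genes."""
        from estronet import gcn_gene_filter, log2fc_profiles, pearson_profiles

        expr, deg, truth = noisefree_dataset
        kept, _ = gcn_gene_filter(deg)
        prof = log2fc_profiles(expr)
        kept_prof = ProfileMatrix(prof.data.loc[kept], prof.tissues, prof.days)
        r = pearson_profiles(kept_prof)
        from estronet import build_network, pcit_mask

        mask, _ = pcit_mask(r)
        assignment = assign_tissue(kept_prof)
        net = build_network(r, mask, 0.90, node_attrs=assignment.table)
        part = partition_network(net, assignment)

        assert part.bridging == truth.bridging_genes
        primary = truth.primary_tissue()
        for tissue in TISSUES:
            expected = {g for g in kept if primary.get(g) == tissue}
            assert set(part.subnetworks[tissue].nodes) == expected
        labels = assignment.label_map()
        for u, v in net.edges:
            if labels[u] != labels[v]:
                assert u in part.bridging and v in part.bridging
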