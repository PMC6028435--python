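import numpy as np
import pytest

from degnet.network import (
    PathwayGraph,
    integrate,
    mark_degs,
    parse_pathway,
    select_hub_degs,
    write_network_tables,
)


KGML_BASIC = """<?xml version="1.0"?>
<pathway name="p1">
  <entry id="1" type="gene" name="A"/>
  <entry id="2" type="gene" name="B"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""

KGML_GROUP = """<?xml version="1.0"?>
<pathway name="p2">
  <entry id="1" type="gene" name="A"/>
  <entry id="2" type="gene" name="B"/>
  <entry id="3" type="gene" name="C"/>
  <entry id="4" type="group" name="undefined">
    <component id="1"/>
    <component id="2"/>
  </entry>
  <relation entry1="4" entry2="3" type="PPrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""

KGML_MAP = """<?xml version="1.0"?>
<pathway name="p3">
  <entry id="1" type="gene" name="A"/>
  <entry id="2" type="map" name="path:hsa04210"/>
  <relation entry1="1" entry2="2" type="maplink">
    <subtype name="compound" value="x"/>
  </relation>
</pathway>
"""


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def chain_graph(keys, pathway="P"):
    """Simple path graph over single-gene nodes, for assembling fixtures."""
    g = PathwayGraph()
    for k in keys:
        g.add_node((k,), {pathway})
    for a, b in zip(keys, keys[1:]):
        g.add_edge((a,), (b,), {"activation"}, {pathway})
    return g


class TestParse:
    def test_two_entries_one_relation(self, tmp_path):
        g = parse_pathway(write(tmp_path, "p.xml", KGML_BASIC))
        assert g.n_nodes == 2 and g.n_edges == 1

    def test_group_relation_expanded_to_components(self, tmp_path):
        g = parse_pathway(write(tmp_path, "p.xml", KGML_GROUP))
        assert g.n_nodes == 3 and g.n_edges == 2
        assert g.degree(("C",)) == 2

    def test_map_entry_and_its_relations_dropped(self, tmp_path):
        g = parse_pathway(write(tmp_path, "p.xml", KGML_MAP))
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_missing_entry_reference_is_an_error(self, tmp_path):
        bad = KGML_BASIC.replace('entry2="2"', 'entry2="99"')
        with pytest.raises(ValueError, match="99"):
            parse_pathway(write(tmp_path, "p.xml", bad))

    def test_multi_gene_entries_key_by_sorted_gene_set(self, tmp_path):
        xml = KGML_BASIC.replace('name="A"', 'name="B A"').replace(
            '<entry id="2" type="gene" name="B"/>', '<entry id="2" type="gene" name="C"/>')
        g = parse_pathway(write(tmp_path, "p.xml", xml))
        assert ("A", "B") in g.graph.nodes


class TestIntegrate:
    def test_same_pathway_twice_merges_with_both_provenances(self, tmp_path):
        g1 = parse_pathway(write(tmp_path, "a.xml", KGML_BASIC), "P1")
        g2 = parse_pathway(write(tmp_path, "b.xml", KGML_BASIC), "P2")
        merged = integrate([g1, g2])
        assert merged.n_nodes == 2 and merged.n_edges == 1
        assert merged.graph.nodes[("A",)]["pathways"] == {"P1", "P2"}

    def test_shared_node_accumulates_degree_across_pathways(self):
        merged = integrate([chain_graph(["A", "B"], "P1"), chain_graph(["A", "C"], "P2")])
        assert merged.degree(("A",)) == 2

    def test_disjoint_union_adds_counts(self):
        gs = [chain_graph(["A", "B"], "P1"), chain_graph(["C", "D"], "P2"),
              chain_graph(["E", "F", "G"], "P3")]
        merged = integrate(gs)
        assert merged.n_nodes == 7 and merged.n_edges == 4

    def test_idempotent(self):
        gs = [chain_graph(["A", "B", "C"], "P1"), chain_graph(["B", "D"], "P2")]
        once = integrate(gs)
        twice = integrate([once])
        assert set(once.graph.nodes) == set(twice.graph.nodes)
        assert set(map(frozenset, once.graph.edges)) == set(map(frozenset, twice.graph.edges))

    def test_input_order_invariant(self):
        gs = [chain_graph(["A", "B", "C"], "P1"), chain_graph(["B", "D"], "P2"),
              chain_graph(["C", "D", "E"], "P3")]
        fwd = integrate(gs)
        rev = integrate(gs[::-1])
        assert set(fwd.graph.nodes) == set(rev.graph.nodes)
        assert set(map(frozenset, fwd.graph.edges)) == set(map(frozenset, rev.graph.edges))
        assert all(fwd.degree(k) == rev.degree(k) for k in fwd.graph.nodes)

    def test_degrees_match_incidence_count_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(10, 200))
            keys = [f"n{i}" for i in range(n)]
            edges = set()
            for _ in range(int(rng.integers(n, 3 * n))):
                a, b = rng.choice(n, size=2, replace=False)
                edges.add(frozenset((keys[a], keys[b])))
            g = PathwayGraph()
            for k in keys:
                g.add_node((k,), {"P"})
            for e in edges:
                a, b = sorted(e)
                g.add_edge((a,), (b,), {"r"}, {"P"})
            for k in keys:
                brute = sum(1 for e in edges if k in e)
                assert g.degree((k,)) == brute


class TestHubSelection:
    def graph_with_degrees(self, degrees):
        """Star-based construction: node i gets the requested degree."""
        g = PathwayGraph()
        hubs = [f"h{i}" for i in range(len(degrees))]
        for h in hubs:
            g.add_node((h,), {"P"})
        leaf = 0
        for h, d in zip(hubs, degrees):
            for _ in range(d):
                g.add_node((f"x{leaf}",), {"P"})
                g.add_edge((h,), (f"x{leaf}",), {"r"}, {"P"})
                leaf += 1
        return g, hubs

    def test_unique_maximum_selected_alone(self):
        g = PathwayGraph()
        for k in "ABCDEFGHIJ":
            g.add_node((k,), {"P"})
        # A gets degree 9 (edges to all others); everything else degree 1
        for k in "BCDEFGHIJ":
            g.add_edge(("A",), (k,), {"r"}, {"P"})
        sel = select_hub_degs(mark_degs(g, set()), 0.10)
        assert sel.top_nodes == (("A",),)

    def test_boundary_ties_included(self):
        g, hubs = self.graph_with_degrees([5, 5, 5, 5])
        # |V| = 24, k = ceil(2.4) = 3, cutoff 5 → all four degree-5 nodes kept
        sel = select_hub_degs(mark_degs(g, set()), 0.10)
        assert {n[0] for n in sel.top_nodes} == set(hubs)

    def test_ties_excluded_when_requested(self):
        g, _ = self.graph_with_degrees([5, 5, 5, 5])
        sel = select_hub_degs(mark_degs(g, set()), 0.10, include_ties=False)
        assert len(sel.top_nodes) == 3

    def test_unmarked_top_node_kept_out_of_hub_gene_list(self):
        g, hubs = self.graph_with_degrees([6, 6])
        mark_degs(g, {"h0": "up"})
        sel = select_hub_degs(g, 0.10)  # |V|=14, k=2 → both degree-6 nodes
        assert {n[0] for n in sel.top_nodes} == {"h0", "h1"}
        assert sel.hub_nodes == (("h0",),)
        assert sel.hub_genes == ("h0",)

    def test_full_fraction_returns_exactly_deg_marked_nodes(self):
        g, _ = self.graph_with_degrees([3, 2])
        mark_degs(g, {"h1": "down", "x0": "up"})
        sel = select_hub_degs(g, 1.0)
        assert set(sel.hub_nodes) == {("h1",), ("x0",)}
        assert sel.hub_genes_down == ("h1",) and sel.hub_genes_up == ("x0",)

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_hub_degs(PathwayGraph(), 0.10)

    def test_mark_degs_by_intersection(self):
        g = PathwayGraph()
        g.add_node(("A", "B"), {"P"})
        g.add_node(("C",), {"P"})
        mark_degs(g, {"B"})
        assert g.graph.nodes[("A", "B")]["is_deg"]
        assert not g.graph.nodes[("C",)]["is_deg"]
        mark_degs(g, set())
        assert not any(d["is_deg"] for _, d in g.graph.nodes(data=True))


def test_exported_tables_are_deterministic(tmp_path):
    g = chain_graph(["B", "A", "C"], "P1")
    mark_degs(g, {"A": "up"})
    n1, e1 = tmp_path / "n1.tsv", tmp_path / "e1.tsv"
    n2, e2 = tmp_path / "n2.tsv", tmp_path / "e2.tsv"
    write_network_tables(g, n1, e1)
    write_network_tables(g, n2, e2)
    assert n1.read_bytes() == n2.read_bytes() and e1.read_bytes() == e2.read_bytes()
    assert "node_key\tgenes\tdegree\tis_deg\tpathways" in n1.read_text()
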