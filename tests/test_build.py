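"""Network construction: modifiers, group expansion, propagation, variants."""

import random

import networkx as nx
import pytest

from keggtopo import (
    aggregate_parallel_edges,
    attach_modifier,
    build_base_graph,
    build_network,
    expand_groups,
    naive_gene_network,
    parse_kgml,
    propagate_non_genes,
    strip_modifier,
)
from keggtopo.build import EdgeRow, gene_keep, mixed_keep, GroupCycleError
from keggtopo.fixtures import EntrySpec, FixtureSpec, RelationSpec, make_kgml
from keggtopo.metrics import edge_set, to_graph

from conftest import make_test_graph, oracle_propagate_pairs, random_labelled_digraph


@pytest.mark.parametrize("accession,entry_id,expected", [
    ("cpd:C00035", 92, "cpd:C00035-92"),
    ("hsa:10000", 23, "hsa:10000-23"),
    ("path:hsa04014", 0, "path:hsa04014-0"),
])
def test_attach_modifier(accession, entry_id, expected):
    assert attach_modifier(accession, entry_id) == expected


@pytest.mark.parametrize("node,expected", [
    ("hsa:10000-23", "hsa:10000"),
    ("hsa:10000", "hsa:10000"),
    ("cpd:C00165-198", "cpd:C00165"),
    ("path:hsa04014-0", "path:hsa04014"),
])
def test_strip_modifier(node, expected):
    assert strip_modifier(node) == expected


class TestBaseGraph:
    def test_cartesian_expansion_of_multi_accession_entries(self):
        p = make_test_graph(
            [(5, "gene", ("hsa:1", "hsa:2")), (6, "gene", "hsa:3")],
            [(5, 6)])
        g = build_base_graph(p)
        assert set(g) == {"hsa:1-5", "hsa:2-5", "hsa:3-6"}
        assert set(g.edges()) == {("hsa:1-5", "hsa:3-6"), ("hsa:2-5", "hsa:3-6")}

    def test_no_relations_gives_edgeless_graph(self):
        p = make_test_graph([(1, "gene", "hsa:1"), (2, "gene", "hsa:2")], [])
        g = build_base_graph(p)
        assert g.number_of_edges() == 0 and len(g) == 2

    def test_shared_accession_yields_distinct_nodes(self):
        p = make_test_graph(
            [(10, "compound", "cpd:C00165"), (20, "compound", "cpd:C00165")], [])
        g = build_base_graph(p)
        assert set(g) == {"cpd:C00165-10", "cpd:C00165-20"}

    def test_binding_association_is_bidirectional(self):
        p = make_test_graph(
            [(1, "gene", "hsa:1"), (2, "gene", "hsa:2")],
            [(1, 2, "PPrel", (("binding/association", "---"),))])
        g = build_base_graph(p)
        assert g.has_edge("hsa:1-1", "hsa:2-2")
        assert g.has_edge("hsa:2-2", "hsa:1-1")


class TestExpandGroups:
    def test_group_edges_reattach_and_clique_added(self, group_spec):
        p = parse_kgml(make_kgml(group_spec))
        g = expand_groups(build_base_graph(p), p)
        assert "undefined-7" not in g
        edges = set(g.edges())
        assert ("hsa:1-1", "hsa:3-3") in edges
        assert ("hsa:2-2", "hsa:3-3") in edges
        clique = [d for _, _, d in g.edges(data=True)
                  if d["provenance"] == "clique"]
        assert len(clique) == 1
        assert clique[0]["names"] == ["clique"] and clique[0]["values"] == ["Custom"]

    def test_graph_without_groups_unchanged(self, shared_pathway):
        g = build_base_graph(shared_pathway)
        g2 = expand_groups(g, shared_pathway)
        assert set(g) == set(g2)
        assert g.number_of_edges() == g2.number_of_edges()

    def test_single_member_group_has_no_clique_edge(self):
        p = make_test_graph(
            [(1, "gene", "hsa:1"), (3, "gene", "hsa:3")], [])
        p.entries[7] = type(p.entries[1])(entry_id=7, entry_type="group",
                                          components=[1])
        from keggtopo.kgml import KgmlRelation
        p.relations.append(KgmlRelation(7, 3, "PPrel",
                                        [("activation", "-->")]))
        g = expand_groups(build_base_graph(p), p)
        assert set(g.edges()) == {("hsa:1-1", "hsa:3-3")}

    def test_chained_groups_resolve_to_leaf_members(self):
        spec = FixtureSpec(entries=[
            EntrySpec(1, "gene", ("hsa:1",)),
            EntrySpec(2, "gene", ("hsa:2",)),
            EntrySpec(3, "gene", ("hsa:3",)),
            EntrySpec(8, "group", components=(1,)),
            EntrySpec(7, "group", components=(8, 2)),
        ], relations=[RelationSpec(7, 3)])
        p = parse_kgml(make_kgml(spec))
        g = expand_groups(build_base_graph(p), p)
        assert ("hsa:1-1", "hsa:3-3") in set(g.edges())
        assert ("hsa:2-2", "hsa:3-3") in set(g.edges())

    def test_cyclic_groups_raise_naming_ids(self):
        spec = FixtureSpec(entries=[
            EntrySpec(7, "group", components=(8,)),
            EntrySpec(8, "group", components=(7,)),
        ])
        p = parse_kgml(make_kgml(spec))
        with pytest.raises(GroupCycleError, match="7"):
            expand_groups(build_base_graph(p), p)


class TestPropagation:
    def test_gene_compound_gene_bridges_and_deletes(self):
        p = make_test_graph(
            [(1, "gene", "hsa:8503"), (2, "compound", "cpd:C1"),
             (3, "gene", "hsa:7074")],
            [(1, 2, "PCrel", (("activation", "-->"),)),
             (2, 3, "PCrel", (("activation", "-->"),))])
        g = propagate_non_genes(build_base_graph(p), gene_keep("hsa"))
        assert set(g) == {"hsa:8503-1", "hsa:7074-3"}
        (_, _, d), = g.edges(data=True)
        assert (d["types"], d["values"], d["names"]) == (
            ["CPp"], ["Custom"], ["compound propagation"])

    def test_compound_free_graph_unchanged(self):
        p = make_test_graph(
            [(1, "gene", "hsa:1"), (2, "gene", "hsa:2")], [(1, 2)])
        g0 = build_base_graph(p)
        g = propagate_non_genes(g0, gene_keep("hsa"))
        assert set(g) == set(g0)
        assert set(g.edges()) == set(g0.edges())

    def test_branched_chain_only_forward_paths_bridge(self):
        # g1 -> c1 -> c2 -> g2 and c1 -> g3: expect g1->g2, g1->g3 only
        p = make_test_graph(
            [(1, "gene", "hsa:1"), (2, "compound", "cpd:C1"),
             (3, "compound", "cpd:C2"), (4, "gene", "hsa:2"),
             (5, "gene", "hsa:3")],
            [(1, 2, "PCrel", ()), (2, 3, "PCrel", ()), (3, 4, "PCrel", ()),
             (2, 5, "PCrel", ())])
        g = propagate_non_genes(build_base_graph(p), gene_keep("hsa"))
        assert set(g.edges()) == {("hsa:1-1", "hsa:2-4"), ("hsa:1-1", "hsa:3-5")}

    def test_matches_exhaustive_path_oracle_on_random_graphs(self):
        rng = random.Random(20240901)
        for _ in range(60):
            g = random_labelled_digraph(rng, max_nodes=12)
            keep = gene_keep("hsa")
            result = propagate_non_genes(g, keep)
            assert set(result.edges()) == oracle_propagate_pairs(g, keep)

    def test_original_edge_precedence_over_propagated(self):
        # direct g1->g2 plus g1->c->g2: original metadata must stand alone
        p = make_test_graph(
            [(1, "gene", "hsa:1"), (2, "compound", "cpd:C1"),
             (3, "gene", "hsa:2")],
            [(1, 3), (1, 2, "PCrel", ()), (2, 3, "PCrel", ())])
        t = build_network(p, "gene", unique=True)
        (row,) = t.rows
        assert row.names == "activation" and row.provenance == "original"


class TestAggregation:
    def test_parallel_originals_comma_join(self):
        rows = [EdgeRow("A", "B", "PPrel", "-->", "activation"),
                EdgeRow("A", "B", "PPrel", "-->", "activation")]
        (out,) = aggregate_parallel_edges(rows)
        assert (out.types, out.values, out.names) == (
            "PPrel, PPrel", "-->,-->", "activation, activation")

    def test_unique_rows_unchanged(self):
        rows = [EdgeRow("A", "B", "PPrel", "-->", "activation"),
                EdgeRow("B", "C", "PPrel", "-->", "inhibition")]
        assert aggregate_parallel_edges(rows) == rows

    def test_original_wins_over_propagated(self):
        rows = [EdgeRow("A", "B", "CPp", "Custom", "compound propagation",
                        "compound_propagated"),
                EdgeRow("A", "B", "PPrel", "-->", "activation", "original")]
        (out,) = aggregate_parallel_edges(rows)
        assert out.provenance == "original"
        assert out.names == "activation"

    def test_propagated_duplicates_collapse_to_one(self):
        rows = [EdgeRow("A", "B", "CPp", "Custom", "compound propagation",
                        "compound_propagated")] * 3
        (out,) = aggregate_parallel_edges(rows)
        assert out.names == "compound propagation"


class TestBuildNetwork:
    def test_two_neighborhoods_stay_separate_in_both_suffix_modes(
            self, shared_pathway):
        for unique in (True, False):
            t = build_network(shared_pathway, "gene", unique)
            g = to_graph(edge_set(t))
            assert nx.number_connected_components(g) == 2
        naive = naive_gene_network(shared_pathway)
        assert nx.number_connected_components(to_graph(edge_set(naive))) == 1

    def test_mixed_non_unique_suffix_policy(self, shared_pathway):
        t = build_network(shared_pathway, "mixed", unique=False)
        nodes = t.nodes()
        assert "cpd:C00165-10" in nodes and "cpd:C00165-20" in nodes
        for n in nodes:
            if n.startswith("hsa:"):
                assert strip_modifier(n) == n

    def test_empty_pathway_gives_empty_table(self):
        p = parse_kgml(make_kgml(FixtureSpec()))
        assert build_network(p, "gene").rows == []
        assert build_network(p, "mixed").rows == []

    def test_gene_mode_purity(self, shared_pathway):
        for unique in (True, False):
            t = build_network(shared_pathway, "gene", unique)
            for n in t.nodes():
                assert n.startswith("hsa:")

    def test_map_nodes_kept_in_mixed_transited_in_gene_mode(self):
        p = make_test_graph(
            [(1, "gene", "hsa:1"), (2, "map", "path:hsa04010"),
             (3, "gene", "hsa:2")],
            [(1, 2, "maplink", ()), (2, 3, "maplink", ())])
        mixed = build_network(p, "mixed", unique=False)
        assert any(n.startswith("path:") for n in mixed.nodes())
        gene = build_network(p, "gene", unique=False)
        assert gene.nodes() == {"hsa:1", "hsa:2"}
        (row,) = gene.rows
        assert row.names == "compound propagation"

    def test_undefined_placeholders_transit_in_mixed_mode(self):
        xml = ('<pathway name="p" org="hsa" number="1" title="">'
               '<entry id="1" name="hsa:1" type="gene"/>'
               '<entry id="2" name="undefined" type="ortholog"/>'
               '<entry id="3" name="cpd:C1" type="compound"/>'
               '<relation entry1="1" entry2="2" type="PPrel"/>'
               '<relation entry1="2" entry2="3" type="PPrel"/></pathway>')
        t = build_network(parse_kgml(xml), "mixed", unique=False)
        assert t.nodes() == {"hsa:1", "cpd:C1-3"}

    def test_output_sorted_and_byte_identical_between_runs(
            self, shared_pathway, tmp_path):
        paths = []
        for i in (1, 2):
            t = build_network(shared_pathway, "mixed", unique=True)
            f = tmp_path / f"run{i}.tsv"
            t.write_tsv(f)
            paths.append(f.read_bytes())
        assert paths[0] == paths[1]
        t = build_network(shared_pathway, "mixed", unique=True)
        assert t.rows == sorted(t.rows, key=lambda r: (r.entry1, r.entry2))

    def test_stripping_happens_after_propagation_not_before(self, shared_pathway):
        """Guard: non-unique gene output must not bridge the neighborhoods."""
        t = build_network(shared_pathway, "gene", unique=False)
        gene_sets = [{"hsa:5335", "hsa:5578"}, {"hsa:5337", "hsa:10125"}]
        for row in t.rows:
            for s in gene_sets:
                assert not ({row.entry1, row.entry2} & s) or \
                    {row.entry1, row.entry2} <= s

    def test_component_monotonicity_on_random_fixtures(self):
        from keggtopo.fixtures import random_pathway
        for seed in range(10):
            p = parse_kgml(random_pathway(8, 4, 3, seed=seed))
            uniq = build_network(p, "gene", unique=True)
            naive = naive_gene_network(p)
            cu = nx.number_connected_components(to_graph(edge_set(uniq)))
            cn = nx.number_connected_components(to_graph(edge_set(naive)))
            assert cu >= cn
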