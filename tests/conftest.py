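import random

import networkx as nx
import pytest

from keggtopo import fixtures, parse_kgml
from keggtopo.fixtures import EntrySpec, FixtureSpec, RelationSpec


@pytest.fixture
def shared_xml():
    return fixtures.make_shared_compound_scenario()


@pytest.fixture
def shared_pathway(shared_xml):
    return parse_kgml(shared_xml)


@pytest.fixture
def group_spec():
    """Group of two genes with one external activation onto a third gene."""
    return FixtureSpec(
        org="hsa",
        number="90002",
        entries=[
            EntrySpec(1, "gene", ("hsa:1",), x=80, y=80),
            EntrySpec(2, "gene", ("hsa:2",), x=160, y=80),
            EntrySpec(3, "gene", ("hsa:3",), x=240, y=80),
            EntrySpec(7, "group", components=(1, 2)),
        ],
        relations=[RelationSpec(7, 3, "PPrel", (("activation", "-->"),))],
    )


def make_test_graph(entries, relations, org="hsa"):
    """Shortcut: build a parsed Pathway from terse entry/relation tuples.

    entries: (id, type, accession or tuple-of-accessions)
    relations: (id1, id2) or (id1, id2, rel_type, subtypes)
    """
    specs = []
    for eid, etype, accs in entries:
        accs = (accs,) if isinstance(accs, str) else tuple(accs)
        specs.append(EntrySpec(eid, etype, accs, x=80 * eid, y=80))
    rels = []
    for r in relations:
        if len(r) == 2:
            rels.append(RelationSpec(r[0], r[1], "PPrel", (("activation", "-->"),)))
        else:
            rels.append(RelationSpec(*r))
    spec = FixtureSpec(org=org, entries=specs, relations=rels)
    return parse_kgml(fixtures.make_kgml(spec))


def random_labelled_digraph(rng: random.Random, max_nodes: int = 12) -> nx.MultiDiGraph:
    """Random directed graph whose nodes are flagged kept/removable.

    Node attributes mimic what build_base_graph produces: kept nodes carry
    an organism accession, removable ones a compound accession.
    """
    n = rng.randint(2, max_nodes)
    g = nx.MultiDiGraph(org="hsa")
    for i in range(n):
        kept = rng.random() < 0.55
        acc = f"hsa:{i}" if kept else f"cpd:C{i:05d}"
        g.add_node(f"{acc}-{i}", accession=acc, entry_id=i,
                   entry_type="gene" if kept else "compound")
    nodes = list(g)
    n_edges = rng.randint(0, 2 * n)
    for _ in range(n_edges):
        u, w = rng.choice(nodes), rng.choice(nodes)
        if u != w:
            g.add_edge(u, w, types=["PPrel"], values=["-->"],
                       names=["activation"], provenance="original")
    return g


def oracle_propagate_pairs(g: nx.MultiDiGraph, keep) -> set:
    """Exhaustive oracle: ordered kept pairs (u, w) joined by some directed
    path whose interior nodes are all non-kept (direct edges included).

    Enumerates every simple path; independent of the BFS implementation.
    """
    kept = [v for v in g if keep(v, g.nodes[v])]
    pairs = set()
    for u in kept:
        for w in kept:
            if u == w:
                continue
            for path in nx.all_simple_paths(g, u, w):
                if all(not keep(x, g.nodes[x]) for x in path[1:-1]):
                    pairs.add((u, w))
                    break
    return pairs
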