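"""Convert a parsed pathway into mixed or gene-only edge-list networks.

The pipeline mirrors how the KEGG diagram is actually wired:

1. ``build_base_graph`` — one node per (accession, entry id) pair.  The
   entry id is appended as a terminal modifier ("hsa:10000-23"), so an
   accession drawn twice in different neighborhoods stays two nodes.
2. ``expand_groups`` — AND/OR complexes are replaced by their members;
   edges incident to the group re-attach to every member and the members
   are tied together with "clique" edges.
3. ``propagate_non_genes`` — nodes that must not appear in the output
   (compounds and map links in gene mode, undefined placeholders in mixed
   mode) are bridged over: any two kept nodes connected by a directed path
   whose interior is entirely removable gain a direct "compound
   propagation" edge before the removable nodes are deleted.  This keeps
   the graph connected exactly where the drawn pathway was.
4. Suffix policy + ``aggregate_parallel_edges`` — terminal modifiers are
   kept or stripped per the requested output variant, parallel edges are
   merged into comma-joined metadata, and rows are sorted.

Stripping terminal modifiers *before* propagation (what conventional
parsers effectively do) merges duplicated accessions and can bridge
distant neighborhoods; ``naive_gene_network`` implements that emulation
for comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx

from .kgml import Pathway

logger = logging.getLogger(__name__)

#: metadata of an edge created by compound propagation
CPP_TYPE, CPP_VALUE, CPP_NAME = "CPp", "Custom", "compound propagation"
#: metadata of a clique edge tying group members together
CLIQUE_TYPE, CLIQUE_VALUE, CLIQUE_NAME = "Custom", "Custom", "clique"

#: KGML value for binding/association; such relations are undirected
UNDIRECTED_VALUE = "---"

_SUFFIX_RE = re.compile(r"-\d+$")


class GroupCycleError(Exception):
    """Group entries reference each other cyclically."""


def attach_modifier(accession: str, entry_id: int) -> str:
    """Append the KGML entry id as a terminal modifier: ``cpd:C00035-92``."""
    return f"{accession}-{entry_id}"


def strip_modifier(node_id: str) -> str:
    """Remove a terminal ``-<digits>`` modifier if present, else identity."""
    return _SUFFIX_RE.sub("", node_id)


@dataclass
class EdgeRow:
    """One interaction row of the tab-separated output.

    ``types``/``values``/``names`` are comma-joined per parallel relation
    (subtype), e.g. ``"PPrel, PPrel" / "-->,-->" / "activation, activation"``.
    ``provenance`` records whether the edge came from the KGML file
    (original) or was inferred (compound_propagated, clique).
    """

    entry1: str
    entry2: str
    types: str
    values: str
    names: str
    provenance: str = "original"


@dataclass
class NetworkTable:
    """Ordered edge rows plus the flags that produced them."""

    rows: list[EdgeRow] = field(default_factory=list)
    mode: str = "gene"
    unique: bool = False
    pathway_id: str = ""

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for r in self.rows:
            out.add(r.entry1)
            out.add(r.entry2)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.entry1, r.entry2, r.types, r.values, r.names) for r in self.rows],
            columns=["entry1", "entry2", "type", "value", "name"],
        )

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("entry1\tentry2\ttype\tvalue\tname\n")
            for r in self.rows:
                fh.write(f"{r.entry1}\t{r.entry2}\t{r.types}\t{r.values}\t{r.names}\n")

    @classmethod
    def read_tsv(cls, path, mode: str = "gene", unique: bool = False,
                 pathway_id: str = "") -> "NetworkTable":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("entry1\tentry2"):
                raise ValueError(f"{path}: not a network table (bad header)")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    parts += [""] * (5 - len(parts))
                e1, e2, t, v, n = parts[:5]
                if n == CPP_NAME:
                    prov = "compound_propagated"
                elif n == CLIQUE_NAME:
                    prov = "clique"
                else:
                    prov = "original"
                rows.append(EdgeRow(e1, e2, t, v, n, prov))
        return cls(rows=rows, mode=mode, unique=unique, pathway_id=pathway_id)


def _node_id(accession: str | None, entry_id: int) -> str:
    # placeholder ids for entries without accessions keep the same
    # "-<entry id>" shape so strip_modifier works uniformly
    return attach_modifier(accession if accession else "undefined", entry_id)


def build_base_graph(pathway: Pathway) -> nx.MultiDiGraph:
    """One node per (accession, entry id); one edge per relation x accession pair.

    Group entries become placeholder nodes for :func:`expand_groups`.
    Relations carrying a binding/association subtype (value ``---``) are
    undirected in KGML and contribute an edge in both directions.
    """
    g = nx.MultiDiGraph(org=pathway.org, pathway_id=pathway.pathway_id)

    nodes_of: dict[int, list[str]] = {}
    for entry in pathway.entries.values():
        if entry.entry_type == "group":
            nid = _node_id(None, entry.entry_id)
            g.add_node(nid, accession="undefined", entry_id=entry.entry_id,
                       entry_type="group")
            nodes_of[entry.entry_id] = [nid]
            continue
        ids = []
        if entry.accessions:
            for acc in entry.accessions:
                nid = _node_id(acc, entry.entry_id)
                g.add_node(nid, accession=acc, entry_id=entry.entry_id,
                           entry_type=entry.entry_type)
                ids.append(nid)
        else:
            nid = _node_id(None, entry.entry_id)
            g.add_node(nid, accession="undefined", entry_id=entry.entry_id,
                       entry_type=entry.entry_type)
            ids.append(nid)
        nodes_of[entry.entry_id] = ids

    for rel in pathway.relations:
        k = max(len(rel.subtypes), 1)
        types = [rel.relation_type] * k
        if rel.subtypes:
            values = [v for _, v in rel.subtypes]
            names = [n for n, _ in rel.subtypes]
        else:
            values = [""]
            names = [""]
        bidirectional = UNDIRECTED_VALUE in values
        for u in nodes_of.get(rel.entry1_id, ()):
            for w in nodes_of.get(rel.entry2_id, ()):
                if u == w:
                    continue
                g.add_edge(u, w, types=list(types), values=list(values),
                           names=list(names), provenance="original")
                if bidirectional:
                    g.add_edge(w, u, types=list(types), values=list(values),
                               names=list(names), provenance="original")
    return g


def _group_members(pathway: Pathway, entry_id: int,
                   _stack: tuple[int, ...] = ()) -> list[int]:
    """Flatten (possibly chained) group membership to non-group entry ids."""
    if entry_id in _stack:
        cycle = " -> ".join(str(i) for i in (*_stack, entry_id))
        raise GroupCycleError(f"cyclic group membership: {cycle}")
    members: list[int] = []
    for cid in pathway.entries[entry_id].components:
        child = pathway.entries.get(cid)
        if child is None:
            continue
        if child.entry_type == "group":
            members.extend(_group_members(pathway, cid, (*_stack, entry_id)))
        else:
            members.append(cid)
    return members


def expand_groups(g: nx.MultiDiGraph, pathway: Pathway) -> nx.MultiDiGraph:
    """Replace AND/OR group placeholders by their member nodes.

    Every edge incident to a group re-attaches to each member node, members
    are pairwise linked with "clique" edges, and the placeholder is removed.
    A group with no components keeps its placeholder (logged); it is later
    transited like any other non-kept node.
    """
    g = g.copy()
    group_entries = [e for e in pathway.entries.values() if e.entry_type == "group"]
    for entry in group_entries:
        gid = _node_id(None, entry.entry_id)
        if gid not in g:
            continue
        member_ids = _group_members(pathway, entry.entry_id)
        member_nodes = [
            n for n, d in g.nodes(data=True) if d.get("entry_id") in set(member_ids)
        ]
        if not member_nodes:
            logger.warning(
                "group entry %d has no resolvable components; placeholder kept",
                entry.entry_id,
            )
            continue
        for u, _, data in list(g.in_edges(gid, data=True)):
            for m in member_nodes:
                if u != m:
                    g.add_edge(u, m, **{k: (list(v) if isinstance(v, list) else v)
                                        for k, v in data.items()})
        for _, w, data in list(g.out_edges(gid, data=True)):
            for m in member_nodes:
                if m != w:
                    g.add_edge(m, w, **{k: (list(v) if isinstance(v, list) else v)
                                        for k, v in data.items()})
        for i, a in enumerate(member_nodes):
            for b in member_nodes[i + 1:]:
                g.add_edge(a, b, types=[CLIQUE_TYPE], values=[CLIQUE_VALUE],
                           names=[CLIQUE_NAME], provenance="clique")
        g.remove_node(gid)
    return g


def propagate_non_genes(g: nx.MultiDiGraph, keep) -> nx.MultiDiGraph:
    """Bridge over nodes rejected by ``keep`` and delete them.

    For every ordered pair (u, w) of kept nodes joined by a directed path
    whose interior nodes are all non-kept, exactly one
    "compound propagation" edge u -> w is added — unless an original edge
    already connects the pair, in which case the original stands alone.
    Self-loops are discarded.  Reachability is computed by breadth-first
    search restricted to non-kept interiors (the shortest-path framework:
    only the existence of a shortest such path matters).
    """
    g = g.copy()
    kept = [n for n in g if keep(n, g.nodes[n])]
    kept_set = set(kept)
    for u in kept:
        frontier = [v for v in g.successors(u) if v not in kept_set]
        visited = set(frontier)
        reached: set[str] = set()
        while frontier:
            x = frontier.pop()
            for y in g.successors(x):
                if y in kept_set:
                    reached.add(y)
                elif y not in visited:
                    visited.add(y)
                    frontier.append(y)
        for w in reached:
            if w == u or g.has_edge(u, w):
                continue
            g.add_edge(u, w, types=[CPP_TYPE], values=[CPP_VALUE],
                       names=[CPP_NAME], provenance="compound_propagated")
    removed = [n for n in g if n not in kept_set]
    g.remove_nodes_from(removed)
    return g


_PROVENANCE_RANK = {"original": 0, "clique": 1, "compound_propagated": 2}


def aggregate_parallel_edges(rows: list[EdgeRow]) -> list[EdgeRow]:
    """Merge duplicate (entry1, entry2) rows into comma-joined metadata.

    Original rows take precedence: when a pair carries both original and
    inferred rows, only the original metadata survives.  Inferred duplicates
    (several propagation paths collapsing onto one pair) reduce to a single
    row rather than repeating their constant metadata.
    """
    order: list[tuple[str, str]] = []
    groups: dict[tuple[str, str], list[EdgeRow]] = {}
    for r in rows:
        key = (r.entry1, r.entry2)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    out: list[EdgeRow] = []
    for key in order:
        bunch = groups[key]
        best = min(_PROVENANCE_RANK[r.provenance] for r in bunch)
        chosen = [r for r in bunch if _PROVENANCE_RANK[r.provenance] == best]
        if best > 0:
            # inferred rows have constant metadata; collapse exact duplicates
            seen = set()
            uniq = []
            for r in chosen:
                sig = (r.types, r.values, r.names)
                if sig not in seen:
                    seen.add(sig)
                    uniq.append(r)
            chosen = uniq
        types = ", ".join(r.types for r in chosen)
        values = ",".join(r.values for r in chosen)
        names = ", ".join(r.names for r in chosen)
        out.append(EdgeRow(key[0], key[1], types, values, names,
                           chosen[0].provenance))
    return out


def gene_keep(org: str):
    """Keep predicate for gene mode: organism-prefixed accessions only."""
    prefix = f"{org}:"

    def _keep(node: str, data: dict) -> bool:
        return data.get("accession", "").startswith(prefix)

    return _keep


def mixed_keep(node: str, data: dict) -> bool:
    """Keep predicate for mixed mode: everything with a real accession
    (genes, compounds, linked maps); only placeholders transit."""
    acc = data.get("accession", "")
    return bool(acc) and acc != "undefined"


def _suffix_policy(node: str, data: dict, mode: str, unique: bool, org: str) -> str:
    if unique:
        return node
    if mode == "gene":
        return strip_modifier(node)
    # mixed, non-unique: gene nodes lose the modifier, everything else keeps it
    if data.get("accession", "").startswith(f"{org}:"):
        return strip_modifier(node)
    return node


def build_pruned_graph(pathway: Pathway, mode: str) -> nx.MultiDiGraph:
    """Base graph -> group expansion -> propagation, suffixed node ids.

    Shared by :func:`build_network` and the graphics export (which needs
    the node set including isolated kept nodes).
    """
    if mode not in ("mixed", "gene"):
        raise ValueError(f"mode must be 'mixed' or 'gene', got {mode!r}")
    g = build_base_graph(pathway)
    g = expand_groups(g, pathway)
    keep = gene_keep(pathway.org) if mode == "gene" else mixed_keep
    return propagate_non_genes(g, keep)


def build_network(pathway: Pathway, mode: str, unique: bool = False) -> NetworkTable:
    """Produce one of the four output variants: mixed / mixed unique /
    gene / gene unique.

    Modifier stripping happens *after* propagation, so duplicated
    accessions cannot bridge neighborhoods even in non-unique output;
    stripping merely relabels nodes (merged labels may collapse rows, and
    any resulting self-loops are dropped).
    """
    g = build_pruned_graph(pathway, mode)
    if mode == "gene" and not any(True for _ in g):
        logger.warning("%s: no gene entries; gene network is empty",
                       pathway.pathway_id)

    rows: list[EdgeRow] = []
    dropped_loops = 0
    for u, w, data in g.edges(data=True):
        e1 = _suffix_policy(u, g.nodes[u], mode, unique, pathway.org)
        e2 = _suffix_policy(w, g.nodes[w], mode, unique, pathway.org)
        if e1 == e2:
            dropped_loops += 1
            continue
        rows.append(EdgeRow(e1, e2, ", ".join(data["types"]),
                            ",".join(data["values"]), ", ".join(data["names"]),
                            data["provenance"]))
    if dropped_loops:
        logger.info("%s: dropped %d self-loop(s) after modifier stripping",
                    pathway.pathway_id, dropped_loops)

    rows = aggregate_parallel_edges(rows)
    rows.sort(key=lambda r: (r.entry1, r.entry2))

    isolated = [n for n in g if g.degree(n) == 0]
    if isolated:
        logger.info("%s: %d isolated node(s) omitted from the edge list "
                    "(present in the graphics file)", pathway.pathway_id,
                    len(isolated))
    return NetworkTable(rows=rows, mode=mode, unique=unique,
                        pathway_id=pathway.pathway_id)


def naive_gene_network(pathway: Pathway) -> NetworkTable:
    """Gene-only parse emulating conventional parsers: terminal modifiers
    are stripped *before* propagation, merging duplicated accessions.

    Used as the comparison baseline for topology and modularity analyses;
    not part of the regular output variants.
    """
    g = build_base_graph(pathway)
    g = expand_groups(g, pathway)
    merged = nx.MultiDiGraph(org=pathway.org)
    for n, d in g.nodes(data=True):
        acc = d.get("accession", "undefined")
        label = acc if acc != "undefined" else n  # placeholders stay distinct
        merged.add_node(label, **d)
    for u, w, data in g.edges(data=True):
        lu = g.nodes[u].get("accession") or u
        lw = g.nodes[w].get("accession") or w
        if lu == "undefined":
            lu = u
        if lw == "undefined":
            lw = w
        if lu != lw:
            merged.add_edge(lu, lw, **{k: (list(v) if isinstance(v, list) else v)
                                       for k, v in data.items()})
    pruned = propagate_non_genes(merged, gene_keep(pathway.org))
    rows = [
        EdgeRow(u, w, ", ".join(d["types"]), ",".join(d["values"]),
                ", ".join(d["names"]), d["provenance"])
        for u, w, d in pruned.edges(data=True) if u != w
    ]
    rows = aggregate_parallel_edges(rows)
    rows.sort(key=lambda r: (r.entry1, r.entry2))
    return NetworkTable(rows=rows, mode="gene", unique=False,
                        pathway_id=pathway.pathway_id)
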