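"""Evaluation metrics: per-pathway difference and modularity.

Networks are compared as weightless undirected edge sets.  Two questions
drive the module: how many edges a parse contains that a reference graph
does not (per-pathway difference, ppd), and whether keeping terminal
modifiers yields better-separated community structure (modularity Q of a
detected partition).  Statistical testing of the resulting per-pathway
vectors is left to standard routines; this module produces the vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx
from networkx.algorithms.community import greedy_modularity_communities

from .build import NetworkTable, strip_modifier

logger = logging.getLogger(__name__)

#: an undirected edge: frozenset of two node identifiers
Edge = frozenset
EdgeSet = set

Partition = list[set]
Detector = Callable[[nx.Graph], Partition]


def edge_set(table: NetworkTable, strip: bool = False) -> EdgeSet:
    """Undirected, weightless edge set of a network table.

    ``strip=True`` removes terminal modifiers first (for comparisons
    against references keyed on bare accessions); self-pairs arising from
    stripping are discarded.
    """
    edges: EdgeSet = set()
    for r in table.rows:
        a, b = r.entry1, r.entry2
        if strip:
            a, b = strip_modifier(a), strip_modifier(b)
        if a != b:
            edges.add(frozenset((a, b)))
    return edges


def to_graph(edges: Iterable[Edge]) -> nx.Graph:
    """Undirected graph over an edge set."""
    g = nx.Graph()
    for e in edges:
        a, b = tuple(e)
        g.add_edge(a, b)
    return g


def per_pathway_difference(A: EdgeSet, B: EdgeSet, n: int) -> float:
    """ppd = |A \\ B| / n.

    A is the query parser's edge set, B the reference edge set, n the
    number of pathways compared.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return len(set(A) - set(B)) / n


def partition_modularity(E: EdgeSet, P: Partition, gamma: float = 1.0) -> float:
    """Modularity Q = sum_c [ L_c/m - gamma * (k_c / 2m)^2 ].

    m is the total edge count, L_c the number of intra-community edges of
    community c, and k_c the sum of degrees of its nodes.  The default
    resolution gamma is 1.  Communities must be disjoint and cover the
    node set of E.
    """
    m = len(E)
    if m < 1:
        raise ValueError("modularity is undefined on an edgeless graph")
    nodes = {v for e in E for v in e}
    seen: set = set()
    for c in P:
        if seen & set(c):
            raise ValueError("partition communities are not disjoint")
        seen |= set(c)
    if not nodes <= seen:
        missing = sorted(nodes - seen)[:5]
        raise ValueError(f"partition does not cover the node set "
                         f"(missing e.g. {missing})")

    community_of = {v: i for i, c in enumerate(P) for v in c}
    L = [0] * len(P)
    k = [0] * len(P)
    for e in E:
        a, b = tuple(e) if len(e) == 2 else (next(iter(e)),) * 2
        ca, cb = community_of[a], community_of[b]
        k[ca] += 1
        k[cb] += 1
        if ca == cb:
            L[ca] += 1
    return sum(L[c] / m - gamma * (k[c] / (2 * m)) ** 2 for c in range(len(P)))


def greedy_detector(g: nx.Graph) -> Partition:
    """Default community detector: fast greedy modularity maximisation."""
    return [set(c) for c in greedy_modularity_communities(g)]


@dataclass
class ModularityRecord:
    """Per-pathway modularity comparison of unique vs plain parses."""

    pathway_id: str
    m_unique: int
    m_plain: int
    q_unique: float
    q_plain: float

    @property
    def delta(self) -> float:
        return self.q_unique - self.q_plain


def compare_unique_modularity(
    tables: list[tuple[NetworkTable, NetworkTable]],
    detector: Detector | None = None,
) -> list[ModularityRecord]:
    """Modularity of a detected partition on unique vs plain parses.

    ``tables`` pairs each pathway's terminal-modifier parse with its plain
    counterpart; identifiers are used exactly as parsed (modifiers kept on
    the unique graph, absent from the plain one).  Any detector mapping a
    graph to a partition may be injected; fast greedy modularity is the
    default.  Edgeless pathways are skipped with a log message.
    """
    if detector is None:
        detector = greedy_detector
    records: list[ModularityRecord] = []
    for t_unique, t_plain in tables:
        e_unique = edge_set(t_unique)
        e_plain = edge_set(t_plain)
        if not e_unique or not e_plain:
            logger.warning("%s: edgeless parse; skipped from modularity "
                           "comparison", t_unique.pathway_id)
            continue
        q_u = partition_modularity(e_unique, detector(to_graph(e_unique)))
        q_p = partition_modularity(e_plain, detector(to_graph(e_plain)))
        records.append(ModularityRecord(
            pathway_id=t_unique.pathway_id,
            m_unique=len(e_unique), m_plain=len(e_plain),
            q_unique=q_u, q_plain=q_p,
        ))
    return records


def write_summary(records: list[ModularityRecord], path) -> None:
    """TSV summary: pathway_id, m, Q_unique, Q_plain, delta."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("pathway_id\tm_unique\tm_plain\tQ_unique\tQ_plain\tdelta\n")
        for r in records:
            fh.write(f"{r.pathway_id}\t{r.m_unique}\t{r.m_plain}\t"
                     f"{r.q_unique:.6f}\t{r.q_plain:.6f}\t{r.delta:.6f}\n")
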