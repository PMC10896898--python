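"""Rewrite network tables and graphics maps to Entrez or UniProt identifiers.

Gene accessions (``hsa:10000``) are mapped through a KEGG conversion table
to ``ncbi-geneid:``- or ``up:``-prefixed identifiers; namespace prefixes
are kept so converted files remain unambiguous and reversible.  Terminal
modifiers are detached before lookup and re-attached afterwards, so the
modifier policy of the input is preserved.  Compound (``cpd:``) and
pathway (``path:``) nodes pass through untouched, as do gene accessions
absent from the map (counted and logged).
"""

from __future__ import annotations

import logging
import re
from dataclasses import replace

from .build import EdgeRow, NetworkTable, strip_modifier
from .client import ConvMap
from .graphics import GraphicsMap

logger = logging.getLogger(__name__)

_SUFFIX_RE = re.compile(r"^(?P<acc>.*?)(?P<suffix>-\d+)?$")


class SuffixMismatchError(ValueError):
    """Input carries terminal modifiers but was declared plain (or vice versa)."""


def _split(node_id: str, unique: bool) -> tuple[str, str]:
    if not unique:
        return node_id, ""
    m = _SUFFIX_RE.fullmatch(node_id)
    return m.group("acc"), m.group("suffix") or ""


def _convert_node(node_id: str, cmap: ConvMap, unique: bool) -> str:
    acc, suffix = _split(node_id, unique)
    if acc in cmap.mapping:
        return cmap.mapping[acc] + suffix
    if not unique and node_id != strip_modifier(node_id) \
            and strip_modifier(node_id) in cmap.mapping:
        raise SuffixMismatchError(
            f"node {node_id!r} carries a terminal modifier; pass unique=True "
            "(--unique) for files produced with terminal modifiers"
        )
    return node_id


def convert_table(table: NetworkTable, cmap: ConvMap, unique: bool = False) -> NetworkTable:
    """Return a copy of ``table`` with gene identifiers rewritten via ``cmap``.

    Row count, row order and all metadata columns are preserved exactly;
    only the entry1/entry2 identifier columns change.
    """
    unmapped: set[str] = set()
    rows: list[EdgeRow] = []
    for r in table.rows:
        e1 = _convert_node(r.entry1, cmap, unique)
        e2 = _convert_node(r.entry2, cmap, unique)
        for old, new in ((r.entry1, e1), (r.entry2, e2)):
            acc, _ = _split(old, unique)
            if new == old and acc.startswith(f"{cmap.source_db}:"):
                unmapped.add(acc)
        rows.append(replace(r, entry1=e1, entry2=e2))
    if unmapped:
        logger.info("%d gene accession(s) had no %s mapping and passed through "
                    "unchanged", len(unmapped), cmap.target_db)
    return NetworkTable(rows=rows, mode=table.mode, unique=table.unique,
                        pathway_id=table.pathway_id)


def convert_graphics(gmap: GraphicsMap, cmap: ConvMap, unique: bool = False) -> GraphicsMap:
    """Same contract as :func:`convert_table`, applied to the map keys.

    Coordinates are preserved untouched.
    """
    out = GraphicsMap(pathway_id=gmap.pathway_id)
    for node, xy in gmap.coords.items():
        out.coords[_convert_node(node, cmap, unique)] = xy
    return out
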