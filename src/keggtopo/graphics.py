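"""Node -> (x, y) coordinate export for re-creating KEGG layouts.

Coordinates are KEGG-native: integer pixels, origin top-left, y growing
downward, exactly as printed in the KGML graphics elements.  For plotting
with the usual mathematical convention (y up), negate y — the values are
deliberately not flipped here so the file matches the source map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .build import _suffix_policy, build_pruned_graph
from .kgml import Pathway

logger = logging.getLogger(__name__)


@dataclass
class GraphicsMap:
    """Mapping from node identifier to its KEGG canvas center (x, y)."""

    pathway_id: str = ""
    coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.coords)


def extract_coordinates(pathway: Pathway, mode: str, unique: bool = False) -> GraphicsMap:
    """Coordinates for every node of the corresponding network variant.

    Node identifiers follow the same terminal-modifier policy as
    :func:`keggtopo.build.build_network` with the same ``mode``/``unique``,
    so the file keys match the edge list.  Isolated kept nodes are
    included (the edge-list format cannot express them).  Entries without
    graphics are omitted with a warning; accessions sharing one entry
    share that entry's coordinates.
    """
    g = build_pruned_graph(pathway, mode)
    gmap = GraphicsMap(pathway_id=pathway.pathway_id)
    missing = 0
    for node, data in g.nodes(data=True):
        entry = pathway.entries.get(data["entry_id"])
        if entry is None or not entry.has_graphics:
            missing += 1
            logger.warning("%s: node %s has no graphics coordinates; omitted",
                           pathway.pathway_id, node)
            continue
        key = _suffix_policy(node, data, mode, unique, pathway.org)
        if key in gmap.coords and gmap.coords[key] != (entry.graphics_x, entry.graphics_y):
            logger.info("%s: node %s maps to several coordinates after "
                        "modifier stripping; keeping the first",
                        pathway.pathway_id, key)
            continue
        gmap.coords[key] = (entry.graphics_x, entry.graphics_y)
    if not gmap.coords:
        logger.warning("%s: no graphics coordinates found", pathway.pathway_id)
    return gmap


def write_graphics(gmap: GraphicsMap, path) -> None:
    """Write a tab-separated ``node\\tx\\ty`` file sorted by node id."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tx\ty\n")
        for node in sorted(gmap.coords):
            x, y = gmap.coords[node]
            fh.write(f"{node}\t{x}\t{y}\n")


def read_graphics(path, pathway_id: str = "") -> GraphicsMap:
    """Read a file written by :func:`write_graphics`."""
    gmap = GraphicsMap(pathway_id=pathway_id)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("node\t"):
            raise ValueError(f"{path}: not a graphics file (bad header)")
        for line in fh:
            node, x, y = line.rstrip("\n").split("\t")
            gmap.coords[node] = (int(x), int(y))
    return gmap
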