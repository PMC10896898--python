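"""Export node coordinates for re-creating the KEGG layout.

Extracts the x-y canvas position of every node of the mixed-unique network
and writes the tab-separated graphics file.  Coordinates are KEGG-native
(pixels, origin top-left, y grows downward): negate y when plotting with
the usual mathematical convention.
"""

from pathlib import Path

from keggtopo import extract_coordinates, parse_kgml, write_graphics
from keggtopo.fixtures import make_shared_compound_scenario

pathway = parse_kgml(make_shared_compound_scenario())
gmap = extract_coordinates(pathway, mode="mixed", unique=True)

out = Path("hsa90001_graphics_unique.txt")
write_graphics(gmap, out)

print(f"wrote {out} with {len(gmap)} nodes:")
for node in sorted(gmap.coords):
    x, y = gmap.coords[node]
    print(f"  {node}\t({x}, {y})")
print("Each key matches a node of the mixed-unique edge list; nodes from")
print("the same KGML entry share that entry's drawn position.")
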