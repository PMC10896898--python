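"""Parse a pathway into a gene-only network and show why terminal modifiers matter.

Builds the minimal shared-compound pathway (one compound accession drawn in
two disconnected neighborhoods), parses it with and without topology
preservation, and prints the resulting edge rows and component counts.
"""

import networkx as nx

from keggtopo import build_network, naive_gene_network, parse_kgml
from keggtopo.fixtures import make_shared_compound_scenario
from keggtopo.metrics import edge_set, to_graph

pathway = parse_kgml(make_shared_compound_scenario())

table = build_network(pathway, mode="gene", unique=True)
print("gene network with terminal modifiers:")
for row in table.rows:
    print(f"  {row.entry1}\t{row.entry2}\t{row.types}\t{row.values}\t{row.names}")

naive = naive_gene_network(pathway)
print("\nnaive emulation (modifiers stripped before propagation):")
for row in naive.rows:
    print(f"  {row.entry1}\t{row.entry2}\t{row.types}\t{row.values}\t{row.names}")

cu = nx.number_connected_components(to_graph(edge_set(table)))
cn = nx.number_connected_components(to_graph(edge_set(naive)))
print(f"\ncomponents: modifier-preserving = {cu}, naive = {cn}")
print("The compound sits in two disconnected neighborhoods; only the")
print("modifier-preserving parse keeps them apart after propagation.")
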