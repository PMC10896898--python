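"""Rewrite a parsed network from KEGG gene ids to Entrez ids.

Uses an in-memory conversion table (normally fetched from the KEGG /conv
endpoint with keggtopo.fetch_conv_map); compounds and unmapped genes pass
through unchanged, and terminal modifiers are preserved.
"""

from keggtopo import ConvMap, build_network, convert_table, parse_kgml
from keggtopo.fixtures import make_shared_compound_scenario

pathway = parse_kgml(make_shared_compound_scenario())
table = build_network(pathway, mode="gene", unique=True)

cmap = ConvMap("hsa", "ncbi-geneid", {
    "hsa:5335": "ncbi-geneid:5335",
    "hsa:5337": "ncbi-geneid:5337",
    "hsa:5578": "ncbi-geneid:5578",
    "hsa:10125": "ncbi-geneid:10125",
})
converted = convert_table(table, cmap, unique=True)

print("entry1\tentry2\ttype\tvalue\tname")
for row in converted.rows:
    print(f"{row.entry1}\t{row.entry2}\t{row.types}\t{row.values}\t{row.names}")
print("\nGene accessions now carry the ncbi-geneid: namespace; the -<id>")
print("terminal modifiers survive conversion, so topology stays intact.")
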