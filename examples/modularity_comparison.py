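"""Compare community modularity of modifier-preserving vs naive parses.

Generates seeded random pathways whose duplicated compound hubs span two
neighborhoods each, parses both ways, detects communities with greedy
modularity maximisation, and reports per-pathway modularity Q (resolution
gamma = 1) and the median gain.
"""

from keggtopo import build_network, naive_gene_network, parse_kgml
from keggtopo.fixtures import random_pathway
from keggtopo.metrics import compare_unique_modularity

pairs = []
for seed in range(10):
    p = parse_kgml(random_pathway(n_genes=12, n_compounds=5,
                                  n_duplicated_hubs=3, seed=seed))
    pairs.append((build_network(p, "gene", unique=True),
                  naive_gene_network(p)))

records = compare_unique_modularity(pairs)
print("pathway\tQ_unique\tQ_naive\tdelta")
for r in records:
    print(f"{r.pathway_id}\t{r.q_unique:.4f}\t{r.q_plain:.4f}\t{r.delta:.4f}")

deltas = sorted(r.delta for r in records)
print(f"\nmedian gain: {deltas[len(deltas) // 2]:.4f}")
print("Positive gains mean the modifier-preserving parse yields")
print("better-separated communities than merging duplicated accessions.")
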