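# keggtopo

Topology-preserving parsing of KEGG pathway maps (KGML) into gene-only and
mixed gene/compound/pathway networks.

## The problem

KEGG pathways can be downloaded as KGML, an XML format in which every drawn
box or circle is an `<entry>` with a numeric per-pathway `id` and a
biological accession (`hsa:10000`, `cpd:C00165`, `path:hsa04014`), and every
arrow is a `<relation>`.  The same accession is often drawn several times in
different — possibly disconnected — neighborhoods of the map (a compound in
an "active" and an "inactive" subnetwork, say).  Parsers that identify nodes
by accession merge those duplicates, and once compounds are *propagated*
(replaced by direct gene–gene edges so a gene-only network stays connected),
that merge bridges neighborhoods the original map keeps apart, inventing
gene–gene interactions that exist in no version of the pathway.

keggtopo avoids this by using the KGML entry id as a **terminal modifier**:
a node is an (accession, entry id) pair written `hsa:10000-23` or
`cpd:C00165-198`, so duplicated accessions stay distinct through group
expansion and compound propagation.  Modifiers are stripped only *after*
propagation (or kept, with `unique=True`), so the output topology always
matches the drawn map.

## The method

For a parsed pathway `P` the pipeline is:

1. **Base graph** — one node per (accession, entry id); relations expand over
   the Cartesian product of their endpoints' accessions; binding/association
   relations (KGML value `---`) count in both directions.
2. **Group expansion** — AND/OR complex entries are replaced by their member
   nodes; incident edges re-attach to every member, and members are joined
   pairwise by `clique` edges.
3. **Compound propagation** — with `K` the set of nodes to keep (organism
   genes in `gene` mode; genes, compounds and linked maps in `mixed` mode),
   every ordered pair (u, w) ∈ K×K connected by a directed path whose
   interior nodes all lie outside K gains one edge labelled
   `CPp / Custom / compound propagation`; non-kept nodes are then deleted.
4. **Suffix policy and aggregation** — modifiers are kept (`unique`) or
   stripped (genes always stripped in non-unique output; compounds and maps
   keep theirs in mixed output); parallel rows merge into comma-joined
   metadata (`PPrel, PPrel` / `-->,-->` / `activation, activation`) with
   original KGML edges taking precedence over inferred ones.

Evaluation metrics: per-pathway difference `ppd(A, B, n) = |A \ B| / n` on
undirected edge sets, and modularity
`Q = Σ_c [L_c/m − γ(k_c/2m)²]` (m edges, L_c intra-community edges, k_c
community degree sum, resolution γ = 1 by default), with greedy modularity
maximisation as the default community detector.

## Worked example

```sh
python examples/parse_gene_network.py
```

prints (the fixture is the minimal two-neighborhood shared-compound case):

```
gene network with terminal modifiers:
  hsa:5335-1	hsa:5578-2	CPp	Custom	compound propagation
  hsa:5337-3	hsa:10125-4	CPp	Custom	compound propagation

naive emulation (modifiers stripped before propagation):
  hsa:5335	hsa:10125	CPp	Custom	compound propagation
  hsa:5335	hsa:5578	CPp	Custom	compound propagation
  hsa:5337	hsa:10125	CPp	Custom	compound propagation
  hsa:5337	hsa:5578	CPp	Custom	compound propagation

components: modifier-preserving = 2, naive = 1
```

The compound `cpd:C00165` is drawn once in each of two disconnected
neighborhoods.  The modifier-preserving parse propagates each copy inside
its own neighborhood (two components, two edges); the naive emulation merges
the copies first and fabricates cross-neighborhood edges (one component).
Other examples: `export_coordinates.py` (x-y layout export),
`convert_identifiers.py` (Entrez/UniProt conversion),
`modularity_comparison.py` (community-structure comparison).

## Command line

```sh
keggtopo get-kgml hsa                 # download all KGML files for a species
keggtopo genes hsa04014.xml --unique  # gene-only network, modifiers kept
keggtopo mixed kgml_folder/ --graphics --names
keggtopo convert hsa04014_gene.tsv --uniprot
```

Parsing writes `<stem>_<mode>[_unique].tsv` (columns
`entry1 entry2 type value name`), `--graphics` adds
`<stem>_graphics[_unique].txt` (`node x y`, KEGG-native y-down pixels), and
`--names` adds a variant with display-name columns.  `convert` rewrites gene
ids to Entrez (default) or UniProt (`--uniprot`); pass `--unique` when the
input carries terminal modifiers, and `--map file.tsv` to supply a
conversion table offline.

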