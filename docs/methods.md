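# Methods

## Data model

A KGML document is parsed into a `Pathway`: entries keyed by their numeric
id, relations as directed (entry1, entry2, type, subtype list) records.
Multi-accession `name` attributes split on whitespace; an entry named
`undefined` (typical of complexes without KEGG Orthology assignments) has an
empty accession list.  Graphics coordinates are stored exactly as printed —
integer pixels, origin top-left, y growing downward.  They are deliberately
not flipped: the export is meant to reproduce KEGG's own canvas, and a user
plotting in the mathematical convention negates y.  `<reaction>` elements
are ignored; all topology and edge metadata used here come from relations
and their subtypes.  Unknown entry types (e.g. `brite`) map to `other` and
behave as non-gene, non-compound nodes.  Relations referencing unknown
entry ids are dropped with a logged count rather than failing the parse,
since real KGML files occasionally contain them.

## Node identity and terminal modifiers

The unit of identity is the (accession, entry id) pair, written
`accession-<entry id>` (`cpd:C00035-92`).  The separator is a single `-`
and stripping removes only a terminal `-<digits>` group, so accessions that
themselves contain dashes are safe.  Entries without accessions get
`undefined-<id>` placeholders so the same stripping rule applies uniformly.

## Group (AND/OR) expansion

Group entries are placeholders whose `<component>` children name member
entries; chained groups flatten recursively (cyclic membership raises an
error naming the entry ids).  Edges incident to the group re-attach to every
member node, and members are pairwise connected by edges labelled
`Custom / Custom / clique` in the type/value/name columns.  The clique rows
are kept in gene-only output when the members are genes: they annotate a
real physical complex.  Only the name and value labels of these rows were
fixed a priori; the type column had no prescribed content and mirrors the
value ("Custom") so inferred rows are visually distinct from KGML relation
types.  A group with no resolvable components keeps its placeholder (logged)
and is later transited like any other removable node.

## Compound propagation

Given a keep-predicate K (organism-prefixed genes in `gene` mode; genes,
compounds and linked `path:` maps in `mixed` mode, where only placeholders
transit), the propagation step adds one `CPp / Custom / compound propagation`
edge for every ordered kept pair (u, w) joined by a directed path whose
interior nodes all lie outside K, then deletes the non-kept nodes.
Implementation is a BFS from each kept node restricted to non-kept
interiors — equivalent to asking whether a shortest such path exists, and
O(kept × (V+E)) overall.  Decisions fixed here:

- Direction is respected: predecessors connect to successors.  KGML encodes
  undirected binding/association with the value `---`; such relations count
  in both directions from the start, so propagation can cross them either way.
- Propagated edges do not inherit traversed subtype glyphs; they always
  carry the constant `CPp / Custom / compound propagation` triple, marking
  them as inferred rather than evidence.
- If an original edge already connects a pair, no propagated edge is added;
  at aggregation time original metadata always wins over inferred metadata.
- Several parallel paths between one pair collapse to a single CPp edge.
- Self-loops are discarded; nodes isolated after propagation appear only in
  the graphics file (an edge list cannot express them) and are logged.

## Output variants and suffix policy

Four variants: `mixed`/`gene` × `unique` on/off.  `unique=True` keeps all
modifiers.  `unique=False` strips modifiers from every node in gene mode and
from gene nodes only in mixed mode — compounds and maps keep theirs so
duplicated non-gene entities remain distinguishable.  Critically, stripping
happens *after* propagation: it relabels nodes but cannot create bridges, so
the non-unique outputs have the same (or coarser, when two parallel paths
collapse) topology as the unique ones, never new connectivity.  Rows merge
per ordered pair with comma-joined metadata in first-seen order (types and
names join with `", "`, values with `","`, matching the documented row
shapes), then sort lexicographically by (entry1, entry2), making repeated
runs byte-identical.

The naive emulation (`naive_gene_network`) strips modifiers *before*
propagation, merging duplicated accessions — the behaviour of conventional
parsers that this package exists to avoid.  It is used as a comparison
baseline only.

## KEGG REST client

All HTTP goes through an injectable transport; the default stdlib transport
waits 0.34 s between requests (≈3 requests/s, KEGG's fair-use ceiling) and
makes 3 attempts with exponential backoff.  KGML files cache on disk as
`<pathway_id>.xml` and are never re-fetched.  Conversion tables come from
`/conv/<target>/<org>` (KEGG → target direction, invertible on demand;
first-listed mapping wins for one-to-many results).  Display names use the
generic `/list/<accession>` endpoint, batched 10 accessions per request:
gene names take the description after the first semicolon (the part before
it is the symbol list), compound names the first listed synonym, pathway
names the whole description field.

## Identifier conversion

Conversion detaches the terminal modifier (when `unique=True`), maps the
accession, and re-attaches the modifier, preserving row counts, order and
all metadata columns.  Non-gene namespaces and unmapped genes pass through
unchanged (counted in the log); target namespaces keep their prefixes
(`ncbi-geneid:`, `up:`) so converted files stay unambiguous and reversible.
Passing a modifier-bearing file without `unique=True` is detected (a node
whose stripped form is mappable) and raised as an actionable error.

## Metrics

Networks are compared as weightless undirected edge sets (self-pairs
removed).  `per_pathway_difference(A, B, n) = |A \ B| / n`.
`partition_modularity` evaluates
`Q = Σ_c [L_c/m − γ(k_c/2m)²]` directly from the edge set and a disjoint,
covering partition; γ defaults to 1.  The formula is implemented here and
cross-checked in tests against networkx's modularity over exhaustive
partition enumerations of small graphs — the two routes stay independent.
`compare_unique_modularity` accepts any detector mapping a graph to a
partition (greedy modularity maximisation by default, so externally supplied
partitions from other algorithms slot in) and reports per-pathway
(Q_unique, Q_plain, delta) vectors; statistical testing of those vectors is
delegated to standard routines rather than reimplemented.  Modifiers are
used exactly as parsed: kept on unique graphs, absent from plain ones.

## Synthetic data

The fixtures module generates valid KGML.  `make_shared_compound_scenario`
is the minimal duplicated-compound instance: two disconnected
gene→compound→gene chains sharing one compound accession (`cpd:C00165`,
the diacylglycerol case that motivates the design), so the correct gene
parse has two components and the naive merge has one.  `random_pathway`
emulates a pathway collection at desk scale: genes are partitioned into
`n_duplicated_hubs + 1` (≥2) disconnected clusters, each internally
connected by a gene backbone chain plus random extra gene–gene and
gene–compound–gene links; every duplicated hub is a compound accession with
two entries wired into *different* clusters.  Defaults used in tests and in
the acceptance script — 12 genes, 5 compounds, 3 duplicated hubs, 20 seeds —
keep each run well under a minute while giving every cluster a non-trivial
community.  Fixture coordinates sit on an 80 px grid so graphics tests see
distinct deterministic values.

What the generator does not emulate: KEGG's biological content, realistic
relation-subtype frequencies, group/complex nesting depth beyond what tests
construct explicitly, and the scale of full organism pathway collections.
Passing tests therefore demonstrate the algorithmic contracts (topology
preservation, propagation correctness, metadata shapes, metric values), not
fidelity to any particular real pathway; live-API tests cover the real-data
entry point and run only when the network is reachable.

## Numerical and degenerate-input choices

Modularity requires at least one edge (error otherwise) and a disjoint,
covering partition (error otherwise); `ppd` requires n ≥ 1.  Edgeless
pathways are skipped (logged) in modularity comparisons.  Empty pathways
parse to empty tables; gene mode on a pathway with no genes warns and
returns an empty table.  Sorting ties break lexicographically; all output
files are UTF-8 with `\n` line endings.

## Known limitations

- Reaction stoichiometry and global/overview maps (`ko01100`-style) are out
  of scope; relations are the only edge source.
- Edge weights beyond the KGML subtype glyphs are not inferred.
- One-to-many identifier mappings keep the first listed target; alternatives
  are logged, not emitted.
- Isolated nodes are invisible in edge-list outputs (present in graphics
  files only).
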