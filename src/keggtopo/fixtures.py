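"""Synthetic KGML generation.

Every other module is testable offline against documents produced here:
hand-specified pathways (:func:`make_kgml`), the minimal shared-compound
scenario in which one compound accession sits in two disconnected
neighborhoods (:func:`make_shared_compound_scenario`), and seeded random
pathways with duplicated compound hubs standing in for large pathway
collections (:func:`random_pathway`).

The generated XML is valid KGML as far as the parser is concerned; it
makes no attempt to mimic KEGG's biological content or realistic subtype
frequencies.  Coordinates are laid out on an 80 px grid so graphics tests
see distinct, deterministic values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .kgml import Pathway, KgmlEntry, KgmlRelation, serialize_kgml

GRID = 80  # px spacing of fixture coordinates


class FixtureSpecError(ValueError):
    """A fixture spec contains dangling references."""


@dataclass
class EntrySpec:
    entry_id: int
    entry_type: str = "gene"
    accessions: tuple[str, ...] = ()
    x: int | None = None
    y: int | None = None
    label: str | None = None
    components: tuple[int, ...] = ()


@dataclass
class RelationSpec:
    entry1: int
    entry2: int
    relation_type: str = "PPrel"
    subtypes: tuple[tuple[str, str], ...] = (("activation", "-->"),)


@dataclass
class FixtureSpec:
    org: str = "hsa"
    number: str = "90000"
    title: str = "synthetic pathway"
    entries: list[EntrySpec] = field(default_factory=list)
    relations: list[RelationSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def name(self) -> str:
        return f"path:{self.org}{self.number}"


def spec_to_pathway(spec: FixtureSpec) -> Pathway:
    """The Pathway projection of a fixture spec (reference-checked)."""
    ids = {e.entry_id for e in spec.entries}
    for e in spec.entries:
        for cid in e.components:
            if cid not in ids:
                raise FixtureSpecError(
                    f"entry {e.entry_id} component {cid} does not resolve")
    for r in spec.relations:
        if r.entry1 not in ids or r.entry2 not in ids:
            raise FixtureSpecError(
                f"relation {r.entry1}->{r.entry2} does not resolve")
    p = Pathway(org=spec.org, number=spec.number, name=spec.name,
                title=spec.title)
    for e in spec.entries:
        p.entries[e.entry_id] = KgmlEntry(
            entry_id=e.entry_id, entry_type=e.entry_type,
            accessions=list(e.accessions), graphics_x=e.x, graphics_y=e.y,
            label=e.label, components=list(e.components),
        )
    for r in spec.relations:
        p.relations.append(KgmlRelation(
            entry1_id=r.entry1, entry2_id=r.entry2,
            relation_type=r.relation_type, subtypes=list(r.subtypes),
        ))
    return p


def make_kgml(spec: FixtureSpec) -> str:
    """Well-formed KGML XML text for a fixture spec."""
    return serialize_kgml(spec_to_pathway(spec))


def make_shared_compound_scenario() -> str:
    """Minimal instance of the duplicated-compound failure mode.

    Two disconnected neighborhoods; each contains its own entry for the
    *same* compound accession (cpd:C00165, diacylglycerol in the real
    pathway that motivates this), bridging a different gene pair:

        hsa:5335 -> cpd:C00165(id 10) -> hsa:5578      (neighborhood 1)
        hsa:5337 -> cpd:C00165(id 20) -> hsa:10125     (neighborhood 2)

    A topology-preserving gene parse yields two weakly connected
    components; merging the compound entries by accession before
    propagation collapses them into one.
    """
    spec = FixtureSpec(org="hsa", number="90001",
                       title="shared-compound scenario")
    rows = [
        EntrySpec(1, "gene", ("hsa:5335",), x=GRID, y=GRID),
        EntrySpec(10, "compound", ("cpd:C00165",), x=2 * GRID, y=GRID),
        EntrySpec(2, "gene", ("hsa:5578",), x=3 * GRID, y=GRID),
        EntrySpec(3, "gene", ("hsa:5337",), x=GRID, y=2 * GRID),
        EntrySpec(20, "compound", ("cpd:C00165",), x=2 * GRID, y=2 * GRID),
        EntrySpec(4, "gene", ("hsa:10125",), x=3 * GRID, y=2 * GRID),
    ]
    spec.entries.extend(rows)
    spec.relations.extend([
        RelationSpec(1, 10, "PCrel", (("activation", "-->"),)),
        RelationSpec(10, 2, "PCrel", (("activation", "-->"),)),
        RelationSpec(3, 20, "PCrel", (("activation", "-->"),)),
        RelationSpec(20, 4, "PCrel", (("activation", "-->"),)),
    ])
    return make_kgml(spec)


def random_pathway(n_genes: int, n_compounds: int, n_duplicated_hubs: int,
                   seed: int) -> str:
    """Seeded random pathway with duplicated compound hubs.

    Genes and compounds are partitioned into disconnected neighborhood
    clusters (one more cluster than hubs, at least two).  Each cluster is
    internally connected: a gene backbone chain, extra random gene-gene
    edges, and compounds inserted between gene pairs.  Every duplicated
    hub is one compound accession with two entries placed in *different*
    clusters, each wired gene -> hub -> gene locally — so merging hub
    entries by accession bridges otherwise disconnected clusters.

    Deterministic for a fixed seed.
    """
    if min(n_genes, n_compounds) < 1 or n_duplicated_hubs < 0:
        raise ValueError("sizes must be >= 1 (hubs >= 0)")
    rng = random.Random(seed)
    n_clusters = min(max(2, n_duplicated_hubs + 1), n_genes)
    spec = FixtureSpec(org="hsa", number="91000",
                       title=f"random pathway seed={seed}")

    next_id = 1
    clusters: list[list[int]] = [[] for _ in range(n_clusters)]  # gene entry ids
    for i in range(n_genes):
        c = i % n_clusters
        spec.entries.append(EntrySpec(
            next_id, "gene", (f"hsa:{7000 + i}",),
            x=GRID * (1 + len(clusters[c])), y=GRID * (1 + c)))
        clusters[c].append(next_id)
        next_id += 1

    for c, genes in enumerate(clusters):
        for a, b in zip(genes, genes[1:]):  # backbone chain
            spec.relations.append(RelationSpec(a, b))
        extras = rng.randint(0, max(0, len(genes) - 1))
        for _ in range(extras):
            a, b = rng.sample(genes, 2) if len(genes) >= 2 else (None, None)
            if a is not None:
                spec.relations.append(RelationSpec(
                    a, b, "PPrel", (("binding/association", "---"),)))

    for j in range(n_compounds):
        c = j % n_clusters
        genes = clusters[c]
        spec.entries.append(EntrySpec(
            next_id, "compound", (f"cpd:C{80000 + j}",),
            x=GRID * (10 + j), y=GRID * (1 + c)))
        g1 = rng.choice(genes)
        g2 = rng.choice(genes)
        spec.relations.append(RelationSpec(g1, next_id, "PCrel"))
        spec.relations.append(RelationSpec(next_id, g2, "PCrel"))
        next_id += 1

    for h in range(n_duplicated_hubs):
        acc = f"cpd:C{90000 + h}"
        c1 = h % n_clusters
        c2 = (h + 1) % n_clusters
        for k, c in enumerate((c1, c2)):
            genes = clusters[c]
            spec.entries.append(EntrySpec(
                next_id, "compound", (acc,),
                x=GRID * (20 + h), y=GRID * (1 + c + k)))
            g1 = rng.choice(genes)
            g2 = rng.choice(genes)
            spec.relations.append(RelationSpec(g1, next_id, "PCrel"))
            spec.relations.append(RelationSpec(next_id, g2, "PCrel"))
            next_id += 1

    return make_kgml(spec)
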