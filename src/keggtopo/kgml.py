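"""KGML (KEGG Markup Language) data model, parser, serializer and validator.

A KEGG pathway ships as one XML document per pathway.  Its ``<entry>``
elements are the drawn boxes and circles (genes, compounds, linked maps,
AND/OR groups); ``<relation>`` elements are the arrows between them.  The
crucial quirk of the format is that the *numeric entry id* — not the
biological accession — is the node identity: one accession such as
``cpd:C00165`` may appear as several entries sitting in different, possibly
disconnected, neighborhoods of the map.  The parser therefore keeps entry
ids first-class so downstream code can disambiguate duplicated accessions.

``<reaction>`` elements are ignored: the relation elements carry the
topology and all edge metadata used here.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: entry types recognised verbatim; anything else maps to "other"
ENTRY_TYPES = frozenset(
    {"gene", "compound", "group", "map", "ortholog", "enzyme", "other"}
)

RELATION_TYPES = frozenset(
    {"PPrel", "PCrel", "ECrel", "GErel", "PErel", "maplink"}
)


class KgmlError(Exception):
    """Base class for KGML handling errors."""


class KgmlParseError(KgmlError):
    """Malformed XML; message names the offending line when known."""


class KgmlFormatError(KgmlError):
    """Well-formed XML that is not a KGML pathway document."""


@dataclass
class KgmlEntry:
    """One KGML ``<entry>``.

    ``accessions`` is the whitespace-split ``name`` attribute
    (e.g. ``["hsa:207", "hsa:208"]``); it is empty for groups and for
    entries whose name is the literal ``undefined``.  ``graphics_x`` /
    ``graphics_y`` are KEGG canvas pixels (origin top-left, y grows
    downward), stored exactly as printed in the XML.
    """

    entry_id: int
    entry_type: str
    accessions: list[str] = field(default_factory=list)
    graphics_x: int | None = None
    graphics_y: int | None = None
    label: str | None = None
    components: list[int] = field(default_factory=list)

    @property
    def has_graphics(self) -> bool:
        return self.graphics_x is not None and self.graphics_y is not None


@dataclass
class KgmlRelation:
    """One KGML ``<relation>``: a directed entry1 -> entry2 interaction.

    ``subtypes`` preserves document order as (name, value) pairs, e.g.
    ``[("activation", "-->")]``; the value is the KEGG arrow glyph
    ("-->", "---", "..>", ...).
    """

    entry1_id: int
    entry2_id: int
    relation_type: str
    subtypes: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Pathway:
    """A parsed KGML document."""

    org: str
    number: str
    name: str
    title: str
    entries: dict[int, KgmlEntry] = field(default_factory=dict)
    relations: list[KgmlRelation] = field(default_factory=list)

    @property
    def pathway_id(self) -> str:
        """Short id like ``hsa04014`` (org + number, fallback to name)."""
        if self.org and self.number:
            return f"{self.org}{self.number}"
        return self.name.removeprefix("path:")


@dataclass(frozen=True)
class Issue:
    """A validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    ref: str
    message: str


def _parse_entry(el: ET.Element) -> KgmlEntry:
    entry_id = int(el.get("id"))
    raw_type = el.get("type", "other")
    entry_type = raw_type if raw_type in ENTRY_TYPES else "other"
    name_attr = el.get("name", "") or ""
    if name_attr.strip().lower() == "undefined":
        accessions: list[str] = []
    else:
        accessions = name_attr.split()

    gx = gy = None
    label = None
    g = el.find("graphics")
    if g is not None:
        label = g.get("name")
        x, y = g.get("x"), g.get("y")
        if x is not None and y is not None:
            gx, gy = int(float(x)), int(float(y))

    components = [
        int(c.get("id")) for c in el.findall("component") if c.get("id")
    ]
    return KgmlEntry(
        entry_id=entry_id,
        entry_type=entry_type,
        accessions=accessions,
        graphics_x=gx,
        graphics_y=gy,
        label=label,
        components=components,
    )


def _parse_relation(el: ET.Element) -> KgmlRelation:
    subtypes = [
        (s.get("name", ""), s.get("value", ""))
        for s in el.findall("subtype")
    ]
    return KgmlRelation(
        entry1_id=int(el.get("entry1")),
        entry2_id=int(el.get("entry2")),
        relation_type=el.get("type", ""),
        subtypes=subtypes,
    )


def parse_kgml(xml_text: str) -> Pathway:
    """Parse KGML XML text into a :class:`Pathway`.

    Relations referencing unknown entry ids are dropped with a logged
    warning (their count is reported).  Unknown attributes and elements —
    including ``<reaction>`` — are ignored for forward compatibility
    across KEGG releases.

    Raises
    ------
    KgmlParseError
        if the text is not well-formed XML (message names the line).
    KgmlFormatError
        if the root element is not ``<pathway>``.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:  # exc.position = (line, column)
        line, col = exc.position
        raise KgmlParseError(
            f"malformed XML at line {line}, column {col}: {exc}"
        ) from exc

    if root.tag != "pathway":
        raise KgmlFormatError(
            f"expected <pathway> root element, found <{root.tag}>"
        )

    pathway = Pathway(
        org=root.get("org", ""),
        number=root.get("number", ""),
        name=root.get("name", ""),
        title=root.get("title", ""),
    )
    for el in root.findall("entry"):
        entry = _parse_entry(el)
        pathway.entries[entry.entry_id] = entry

    dropped = 0
    for el in root.findall("relation"):
        rel = _parse_relation(el)
        if rel.entry1_id not in pathway.entries or rel.entry2_id not in pathway.entries:
            dropped += 1
            logger.warning(
                "%s: dropping relation %d->%d referencing unknown entry id",
                pathway.name or "<pathway>",
                rel.entry1_id,
                rel.entry2_id,
            )
            continue
        pathway.relations.append(rel)
    if dropped:
        logger.warning(
            "%s: dropped %d invalid relation(s)", pathway.name or "<pathway>", dropped
        )
    return pathway


def serialize_kgml(pathway: Pathway) -> str:
    """Serialize a :class:`Pathway` back to KGML XML text.

    Entries with empty accession lists are written with ``name="undefined"``
    (the KGML convention for unnamed groups and placeholders), so
    ``parse_kgml(serialize_kgml(p))`` reproduces ``p`` field-by-field.
    """
    root = ET.Element(
        "pathway",
        {
            "name": pathway.name,
            "org": pathway.org,
            "number": pathway.number,
            "title": pathway.title,
        },
    )
    for entry in pathway.entries.values():
        attrs = {
            "id": str(entry.entry_id),
            "name": " ".join(entry.accessions) if entry.accessions else "undefined",
            "type": entry.entry_type,
        }
        el = ET.SubElement(root, "entry", attrs)
        if entry.has_graphics or entry.label is not None:
            gattrs = {}
            if entry.label is not None:
                gattrs["name"] = entry.label
            if entry.has_graphics:
                gattrs["x"] = str(entry.graphics_x)
                gattrs["y"] = str(entry.graphics_y)
            gattrs["type"] = "rectangle"
            ET.SubElement(el, "graphics", gattrs)
        for cid in entry.components:
            ET.SubElement(el, "component", {"id": str(cid)})
    for rel in pathway.relations:
        rel_el = ET.SubElement(
            root,
            "relation",
            {
                "entry1": str(rel.entry1_id),
                "entry2": str(rel.entry2_id),
                "type": rel.relation_type,
            },
        )
        for name, value in rel.subtypes:
            ET.SubElement(rel_el, "subtype", {"name": name, "value": value})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def validate_pathway(pathway: Pathway) -> list[Issue]:
    """Check structural invariants; returns issues, never raises.

    error severity: group components referencing unknown entry ids,
    relation endpoints missing from the entry table.
    warning severity: non-group entries with empty accession lists,
    entries without graphics coordinates.
    """
    issues: list[Issue] = []
    for entry in pathway.entries.values():
        ref = f"entry:{entry.entry_id}"
        for cid in entry.components:
            if cid not in pathway.entries:
                issues.append(
                    Issue("error", ref, f"component id {cid} not in entries")
                )
        if entry.entry_type != "group" and not entry.accessions:
            issues.append(
                Issue("warning", ref, "non-group entry has no accessions")
            )
        if not entry.has_graphics:
            issues.append(Issue("warning", ref, "entry has no graphics coordinates"))
    for i, rel in enumerate(pathway.relations):
        ref = f"relation:{i}"
        for eid in (rel.entry1_id, rel.entry2_id):
            if eid not in pathway.entries:
                issues.append(
                    Issue("error", ref, f"relation endpoint {eid} not in entries")
                )
    return issues
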