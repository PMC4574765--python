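"""Parse KGML (KEGG Markup Language) pathway files into a typed graph.

A KGML document describes one KEGG pathway map as a list of ``entry``
elements (genes, compounds, linked maps, groups, ...) each carrying pixel
graphics, together with ``relation`` and ``reaction`` elements connecting
them.  This module turns such a document into a :class:`PathwayGraph` and
exports it as a plain JSON-ready dict that network viewers (Cytoscape.js
and friends) can consume, with the original image-space coordinates kept
verbatim so overlays line up with the KEGG-drawn pathway image.

Conventions:

* graphics ``x``/``y`` are node centers in the background image's pixel
  space, origin top-left, y increasing downward; no rescaling or flip;
* an entry's ``name`` attribute may hold several space-separated KEGG
  identifiers — all are kept in ``kegg_ids``; the display label is the
  first comma-separated alias of the graphics name;
* ``group`` entries become nodes whose ``member_ids`` reference other
  entries; members stay independent nodes (lossless);
* reactions with several substrates/products expand to the cross product
  of substrate→product edges;
* unknown entry types map to ``NodeType.OTHER`` instead of failing, since
  KGML dialects drift across KEGG releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from lxml import etree

__all__ = [
    "NodeType",
    "EdgeKind",
    "PathwayNode",
    "PathwayEdge",
    "PathwayGraph",
    "KgmlError",
    "KgmlParseError",
    "KgmlStructureError",
    "parse_kgml",
    "graph_to_view_document",
    "view_document_to_graph",
    "pathway_gene_ids",
]


class KgmlError(ValueError):
    """Base class for KGML parsing/validation failures."""


class KgmlParseError(KgmlError):
    """The document is not well-formed XML (message names the line)."""


class KgmlStructureError(KgmlError):
    """Well-formed XML that violates the KGML structure (message names the element)."""


class NodeType(str, Enum):
    GENE = "gene"
    COMPOUND = "compound"
    MAP = "map"
    GROUP = "group"
    ORTHOLOG = "ortholog"
    ENZYME = "enzyme"
    OTHER = "other"


class EdgeKind(str, Enum):
    RELATION = "relation"
    REACTION = "reaction"


@dataclass(frozen=True)
class PathwayNode:
    """One KGML entry with its pixel-space graphics.

    ``x``/``y`` are the node center in the pathway image, origin top-left,
    y downward.  ``member_ids`` is non-empty only for ``group`` nodes.
    """

    entry_id: str
    node_type: NodeType
    kegg_ids: tuple[str, ...]
    label: str
    x: float
    y: float
    width: float
    height: float
    member_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    kind: EdgeKind
    subtype: str = ""


@dataclass
class PathwayGraph:
    pathway_id: str
    title: str = ""
    organism: str = ""
    image_ref: str = ""
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[PathwayEdge] = field(default_factory=list)

    def node_ids(self) -> set[str]:
        return {n.entry_id for n in self.nodes}

    def validate(self) -> None:
        """Check the graph invariants, raising :class:`KgmlStructureError`."""
        ids = [n.entry_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise KgmlStructureError(f"duplicate entry id {dup!r}")
        id_set = set(ids)
        for n in self.nodes:
            if not (n.width > 0 and n.height > 0):
                raise KgmlStructureError(
                    f"entry {n.entry_id!r}: width/height must be positive"
                )
            for m in n.member_ids:
                if m not in id_set:
                    raise KgmlStructureError(
                        f"group entry {n.entry_id!r} references unknown member {m!r}"
                    )
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in id_set:
                    raise KgmlStructureError(
                        f"edge {e.source!r}->{e.target!r} references unknown entry "
                        f"{endpoint!r}"
                    )


_KNOWN_TYPES = {t.value: t for t in NodeType if t is not NodeType.OTHER}


def _entry_to_node(entry: etree._Element) -> PathwayNode:
    entry_id = entry.get("id")
    etype = entry.get("type")
    if entry_id is None or etype is None:
        raise KgmlStructureError(
            f"entry element at line {entry.sourceline} lacks required id/type"
        )
    graphics = entry.find("graphics")
    if graphics is None:
        raise KgmlStructureError(f"entry {entry_id!r} has no graphics element")
    try:
        x = float(graphics.get("x"))
        y = float(graphics.get("y"))
    except (TypeError, ValueError):
        raise KgmlStructureError(
            f"entry {entry_id!r}: graphics x/y missing or non-numeric"
        ) from None
    width = float(graphics.get("width", 46))
    height = float(graphics.get("height", 17))
    gname = graphics.get("name", "") or ""
    label = gname.split(",")[0].strip()
    kegg_ids = tuple((entry.get("name") or "").split())
    members = tuple(
        c.get("id") for c in entry.findall("component") if c.get("id") is not None
    )
    return PathwayNode(
        entry_id=entry_id,
        node_type=_KNOWN_TYPES.get(etype, NodeType.OTHER),
        kegg_ids=kegg_ids,
        label=label,
        x=x,
        y=y,
        width=width,
        height=height,
        member_ids=members,
    )


def parse_kgml(xml_text: str | bytes) -> PathwayGraph:
    """Parse a KGML document into a validated :class:`PathwayGraph`.

    One node per ``entry``, one edge per ``relation``, and one edge per
    substrate→product pair of every ``reaction``.  Relations or reactions
    whose endpoints do not resolve to a parsed entry are dropped (KEGG
    releases occasionally ship dangling references).
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        # KGML ships a DTD reference; never resolve it from the network.
        parser = etree.XMLParser(resolve_entities=False, no_network=True)
        root = etree.fromstring(xml_text, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc
    if root.tag != "pathway":
        raise KgmlStructureError(
            f"root element is {root.tag!r}, expected KGML 'pathway'"
        )

    graph = PathwayGraph(
        pathway_id=root.get("name", "").removeprefix("path:"),
        title=root.get("title", ""),
        organism=root.get("org", ""),
        image_ref=root.get("image", ""),
    )
    for entry in root.findall("entry"):
        graph.nodes.append(_entry_to_node(entry))
    known = graph.node_ids()

    for rel in root.findall("relation"):
        src, dst = rel.get("entry1"), rel.get("entry2")
        if src not in known or dst not in known:
            continue
        sub = rel.find("subtype")
        subtype = sub.get("name", "") if sub is not None else ""
        graph.edges.append(PathwayEdge(src, dst, EdgeKind.RELATION, subtype))

    for rxn in root.findall("reaction"):
        rtype = rxn.get("type", "")
        substrates = [s.get("id") for s in rxn.findall("substrate")]
        products = [p.get("id") for p in rxn.findall("product")]
        for s in substrates:
            for p in products:
                if s in known and p in known:
                    graph.edges.append(PathwayEdge(s, p, EdgeKind.REACTION, rtype))

    graph.validate()
    return graph


def graph_to_view_document(graph: PathwayGraph) -> dict:
    """Export a graph as a JSON-ready network document.

    Node positions are the KGML graphics coordinates unchanged.  The
    document round-trips losslessly through :func:`view_document_to_graph`.
    """
    graph.validate()
    return {
        "pathway_id": graph.pathway_id,
        "title": graph.title,
        "organism": graph.organism,
        "image_ref": graph.image_ref,
        "nodes": [
            {
                "id": n.entry_id,
                "label": n.label,
                "type": n.node_type.value,
                "x": n.x,
                "y": n.y,
                "width": n.width,
                "height": n.height,
                "kegg_ids": list(n.kegg_ids),
                "member_ids": list(n.member_ids),
            }
            for n in graph.nodes
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "kind": e.kind.value,
                "subtype": e.subtype,
            }
            for e in graph.edges
        ],
    }


def view_document_to_graph(doc: dict) -> PathwayGraph:
    """Rebuild a :class:`PathwayGraph` from a view document (inverse export)."""
    graph = PathwayGraph(
        pathway_id=doc.get("pathway_id", ""),
        title=doc.get("title", ""),
        organism=doc.get("organism", ""),
        image_ref=doc.get("image_ref", ""),
        nodes=[
            PathwayNode(
                entry_id=n["id"],
                node_type=NodeType(n["type"]),
                kegg_ids=tuple(n["kegg_ids"]),
                label=n["label"],
                x=float(n["x"]),
                y=float(n["y"]),
                width=float(n["width"]),
                height=float(n["height"]),
                member_ids=tuple(n.get("member_ids", ())),
            )
            for n in doc["nodes"]
        ],
        edges=[
            PathwayEdge(e["source"], e["target"], EdgeKind(e["kind"]), e["subtype"])
            for e in doc["edges"]
        ],
    )
    graph.validate()
    return graph


def pathway_gene_ids(graph: PathwayGraph) -> list[str]:
    """Deduplicated union of KEGG ids over gene nodes, first-occurrence order."""
    seen: set[str] = set()
    out: list[str] = []
    for n in graph.nodes:
        if n.node_type is NodeType.GENE:
            for gid in n.kegg_ids:
                if gid not in seen:
                    seen.add(gid)
                    out.append(gid)
    return out
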