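"""Target-ontology snapshots and OWL output serialization (rdflib-backed).

The optional target ontology serves two purposes: its entity URIs feed ID
collision avoidance, and its ``rdfs:label`` index extends label resolution.
The generated output is a standalone ontology document (own IRI) intended to
be brought into the target via ``owl:imports`` or merging; external classes
referenced but not defined here are listed in a header comment rather than
declared, so reparsing the output counts exactly the generated classes.
"""

from __future__ import annotations

import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS

from .errors import OntoforgeError, SerializationError, TableFormatError
from .manchester import And, HasValue, Named, Not, Only, Or, Some
from .template_engine import GeneratedClass

_ENTITY_TYPES = (OWL.Class, OWL.ObjectProperty, OWL.AnnotationProperty,
                 OWL.DatatypeProperty, OWL.NamedIndividual)


@dataclass
class OntologySnapshot:
    """What the engine needs to know about an existing ontology."""

    ontology_iri: str | None = None
    entity_uris: set[str] = field(default_factory=set)
    label_index: dict[str, str] = field(default_factory=dict)
    source: str = ""


@dataclass(eq=False)
class OutputDocument:
    ontology_iri: str
    classes: list[GeneratedClass]
    declared_properties: set[str]
    serialization: str
    graph: Graph
    external_classes: set[str] = field(default_factory=set)


def _fetch(source) -> bytes:
    s = str(source)
    if s.startswith(("http://", "https://", "file://")):
        try:
            with urllib.request.urlopen(s) as resp:  # noqa: S310 - user-supplied URL
                return resp.read()
        except OSError as exc:
            raise OntoforgeError(f"cannot fetch ontology from {s}: {exc}") from exc
    try:
        return Path(s).read_bytes()
    except OSError as exc:
        raise OntoforgeError(f"cannot read ontology {s}: {exc}") from exc


def _sniff_format(data: bytes) -> str:
    head = data.lstrip()[:256]
    if head.startswith(b"<?xml") or head.startswith(b"<rdf:RDF") or b"<rdf:RDF" in head:
        return "xml"
    return "turtle"


def load_ontology(source) -> OntologySnapshot:
    """Parse an RDF/XML or Turtle ontology (path or URL) into a snapshot.

    The serialization is auto-detected by content sniffing with a fallback
    parse in the other format.  Entities are gathered from type declarations
    and from subject/object positions of subclass and equivalence axioms;
    labels come from ``rdfs:label`` literals on gathered entities.  Duplicate
    labels map to the lexicographically smallest URI, with a warning.
    """
    data = _fetch(source)
    fmt = _sniff_format(data)
    g = Graph()
    try:
        g.parse(data=data, format=fmt)
    except Exception as first:
        other = "turtle" if fmt == "xml" else "xml"
        try:
            g = Graph()
            g.parse(data=data, format=other)
        except Exception:
            raise TableFormatError(
                f"cannot parse ontology {source} as RDF/XML or Turtle: {first}"
            ) from first

    snap = OntologySnapshot(source=str(source))
    for s in g.subjects(RDF.type, OWL.Ontology):
        if isinstance(s, URIRef):
            snap.ontology_iri = str(s)
            break
    for t in _ENTITY_TYPES:
        for s in g.subjects(RDF.type, t):
            if isinstance(s, URIRef):
                snap.entity_uris.add(str(s))
    for p in (RDFS.subClassOf, OWL.equivalentClass):
        for s, o in g.subject_objects(p):
            if isinstance(s, URIRef):
                snap.entity_uris.add(str(s))
            if isinstance(o, URIRef):
                snap.entity_uris.add(str(o))

    for s, o in g.subject_objects(RDFS.label):
        if not (isinstance(s, URIRef) and isinstance(o, Literal)):
            continue
        uri = str(s)
        if uri not in snap.entity_uris:
            continue
        label = str(o)
        if label in snap.label_index and snap.label_index[label] != uri:
            keep = min(snap.label_index[label], uri)
            warnings.warn(
                f"duplicate label {label!r} for <{snap.label_index[label]}> and "
                f"<{uri}>; keeping <{keep}>",
                stacklevel=2,
            )
            snap.label_index[label] = keep
        else:
            snap.label_index[label] = uri
    return snap


def _require_uri(term, context: str) -> URIRef:
    if not term.uri:
        raise SerializationError(f"unresolved term {term.display!r} in {context}")
    return URIRef(term.uri)


def _expr_node(g: Graph, expr, obj_props: set[str], externals: set[str]):
    """Translate a class-expression tree into RDF nodes (recursive)."""
    if isinstance(expr, Named):
        ref = _require_uri(expr.term, "class expression")
        externals.add(str(ref))
        return ref
    if isinstance(expr, (Some, Only)):
        b = BNode()
        p = _require_uri(expr.property, "restriction property")
        obj_props.add(str(p))
        g.add((b, RDF.type, OWL.Restriction))
        g.add((b, OWL.onProperty, p))
        which = OWL.someValuesFrom if isinstance(expr, Some) else OWL.allValuesFrom
        g.add((b, which, _expr_node(g, expr.filler, obj_props, externals)))
        return b
    if isinstance(expr, HasValue):
        b = BNode()
        p = _require_uri(expr.property, "restriction property")
        obj_props.add(str(p))
        g.add((b, RDF.type, OWL.Restriction))
        g.add((b, OWL.onProperty, p))
        g.add((b, OWL.hasValue, _require_uri(expr.value, "value restriction")))
        return b
    if isinstance(expr, (And, Or)):
        b = BNode()
        g.add((b, RDF.type, OWL.Class))
        members = [_expr_node(g, o, obj_props, externals) for o in expr.operands]
        lst = BNode()
        Collection(g, lst, members)
        which = OWL.intersectionOf if isinstance(expr, And) else OWL.unionOf
        g.add((b, which, lst))
        return b
    if isinstance(expr, Not):
        b = BNode()
        g.add((b, RDF.type, OWL.Class))
        g.add((b, OWL.complementOf, _expr_node(g, expr.operand, obj_props, externals)))
        return b
    raise SerializationError(f"cannot serialize expression node {expr!r}")


def write_owl(classes: list[GeneratedClass], ontology_iri: str,
              prefixes: dict[str, str] | None = None, *,
              output_format: str = "rdfxml") -> OutputDocument:
    """Serialize generated classes as a standalone, importable OWL document.

    New classes (``is_new``) get ``owl:Class`` declarations; edited classes
    get axioms only.  Object and annotation properties used by the axioms are
    declared; referenced external classes are assumed external and listed in
    a header comment.  ``output_format`` is ``rdfxml`` or ``turtle``.
    """
    g = Graph()
    for name, uri in (prefixes or {}).items():
        g.bind(name, uri)
    g.add((URIRef(ontology_iri), RDF.type, OWL.Ontology))

    obj_props: set[str] = set()
    ann_props: set[str] = set()
    externals: set[str] = set()
    for c in classes:
        s = URIRef(c.uri)
        if c.is_new:
            g.add((s, RDF.type, OWL.Class))
        for (p, v, tag) in c.annotations:
            ann_props.add(p)
            if tag is None:
                lit = Literal(v)
            elif tag.startswith("@"):
                lit = Literal(v, lang=tag[1:])
            else:
                lit = Literal(v, datatype=URIRef(tag))
            g.add((s, URIRef(p), lit))
        for e in c.superclasses:
            g.add((s, RDFS.subClassOf, _expr_node(g, e, obj_props, externals)))
        for e in c.equivalents:
            g.add((s, OWL.equivalentClass, _expr_node(g, e, obj_props, externals)))

    generated = {c.uri for c in classes}
    externals -= generated
    for u in sorted(obj_props):
        g.add((URIRef(u), RDF.type, OWL.ObjectProperty))
    for u in sorted(ann_props - obj_props):
        g.add((URIRef(u), RDF.type, OWL.AnnotationProperty))

    # the plain xml serializer is lossless with bnode-heavy class expressions
    # (pretty-xml drops assertions on RDF-list nodes)
    fmt = {"rdfxml": "xml", "turtle": "turtle"}.get(output_format)
    if fmt is None:
        raise SerializationError(f"unknown output format: {output_format!r}")
    text = g.serialize(format=fmt)

    if externals:
        note = ("terms assumed to be defined externally (no declaration "
                "emitted here): " + ", ".join(sorted(externals)))
        if fmt == "turtle":
            text = f"# {note}\n" + text
        else:
            lines = text.split("\n", 1)
            if lines[0].startswith("<?xml"):
                text = lines[0] + f"\n<!-- {note} -->\n" + (lines[1] if len(lines) > 1 else "")
            else:
                text = f"<!-- {note} -->\n" + text

    return OutputDocument(
        ontology_iri=ontology_iri,
        classes=list(classes),
        declared_properties=obj_props | (ann_props - obj_props),
        serialization=text,
        graph=g,
        external_classes=externals,
    )
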