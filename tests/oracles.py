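"""Independent oracles used by the test suite.

Everything here is deliberately implemented without reusing the engine's
parsing or counting logic: a reference Manchester parser based on top-level
token-list splitting (vs. the package's streaming recursive descent),
line-based counters for the intermediate document, and rdflib-triple counters
for the OWL output.
"""

from __future__ import annotations

import re

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from ontoforge.manchester import (
    And,
    HasValue,
    Named,
    Not,
    Only,
    Or,
    Some,
    TermRef,
)

# ---------------------------------------------------------------------------
# Reference Manchester parser (token-list splitting)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"'(?:[^']|'')*'|<[^>]*>|\(|\)|[^\s()'<>]+")
_SCHEME = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*://")


def tokens_of(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def structural_tokens(text: str) -> list[str]:
    return [t for t in tokens_of(text) if t not in ("(", ")")]


def _term(tok: str, resolver, uri_start):
    if tok.startswith("'"):
        label = tok[1:-1].replace("''", "'")
        uri = resolver(label)
        if uri is None:
            raise ValueError(f"unknown label {label!r}")
        return TermRef.from_label(label, uri)
    if tok.startswith("<"):
        return TermRef(tok, tok[1:-1])
    if _SCHEME.match(tok):
        return TermRef(tok, tok)
    if uri_start:
        return TermRef(tok, uri_start + tok)
    raise ValueError(f"unresolvable bare token {tok!r}")


def _split_top(toks: list[str], kw: str) -> list[list[str]]:
    parts, buf, depth = [], [], 0
    for t in toks:
        if t == "(":
            depth += 1
        elif t == ")":
            depth -= 1
        if t == kw and depth == 0:
            parts.append(buf)
            buf = []
        else:
            buf.append(t)
    parts.append(buf)
    return parts


def _paren_wrapped(toks: list[str]) -> bool:
    if len(toks) < 2 or toks[0] != "(" or toks[-1] != ")":
        return False
    depth = 0
    for i, t in enumerate(toks):
        if t == "(":
            depth += 1
        elif t == ")":
            depth -= 1
            if depth == 0 and i != len(toks) - 1:
                return False
    return depth == 0


def ref_parse(text: str, resolver, uri_start=None):
    """Reference parse of a Manchester class expression."""
    return _expr(tokens_of(text), resolver, uri_start)


def _expr(toks, resolver, uri_start):
    parts = _split_top(toks, "or")
    if len(parts) > 1:
        return Or(tuple(_conj(p, resolver, uri_start) for p in parts))
    return _conj(parts[0], resolver, uri_start)


def _conj(toks, resolver, uri_start):
    parts = _split_top(toks, "and")
    if len(parts) > 1:
        return And(tuple(_unary(p, resolver, uri_start) for p in parts))
    return _unary(parts[0], resolver, uri_start)


def _unary(toks, resolver, uri_start):
    if not toks:
        raise ValueError("empty expression")
    if toks[0] == "not":
        return Not(_unary(toks[1:], resolver, uri_start))
    if _paren_wrapped(toks):
        return _expr(toks[1:-1], resolver, uri_start)
    if len(toks) >= 3 and toks[1] in ("some", "only"):
        prop = _term(toks[0], resolver, uri_start)
        filler = _primary(toks[2:], resolver, uri_start)
        return Some(prop, filler) if toks[1] == "some" else Only(prop, filler)
    if len(toks) == 3 and toks[1] == "value":
        return HasValue(_term(toks[0], resolver, uri_start),
                        _term(toks[2], resolver, uri_start))
    if len(toks) == 1:
        return Named(_term(toks[0], resolver, uri_start))
    raise ValueError(f"cannot parse token run: {toks}")


def _primary(toks, resolver, uri_start):
    if toks and toks[0] == "not":
        return Not(_primary(toks[1:], resolver, uri_start))
    if _paren_wrapped(toks):
        return _expr(toks[1:-1], resolver, uri_start)
    if len(toks) == 1:
        return Named(_term(toks[0], resolver, uri_start))
    raise ValueError(f"bad restriction filler: {toks}")


# ---------------------------------------------------------------------------
# Intermediate-document counters (line-based)
# ---------------------------------------------------------------------------

def manchester_counts(doc: str) -> dict[str, int]:
    counts = {"classes": 0, "annotations": 0, "superclasses": 0, "equivalents": 0}
    for raw in doc.split("\n"):
        line = raw.strip()
        if line.startswith("Class:"):
            counts["classes"] += 1
        elif line.startswith("Annotations:"):
            counts["annotations"] += 1
        elif line.startswith("SubClassOf:"):
            counts["superclasses"] += 1
        elif line.startswith("EquivalentTo:"):
            counts["equivalents"] += 1
    return counts


# ---------------------------------------------------------------------------
# OWL-output counters (independent rdflib reparse)
# ---------------------------------------------------------------------------

def parse_output(serialization: str) -> Graph:
    g = Graph()
    fmt = "xml" if serialization.lstrip().startswith("<") else "turtle"
    g.parse(data=serialization, format=fmt)
    return g


def rdf_counts(serialization: str) -> dict[str, int]:
    """Axiom counts from an independent reparse of the OWL output.

    ``classes`` counts distinct subject classes carrying a declaration or any
    emitted axiom (so the figure is comparable between the new-classes and
    edit-existing modes); ``declarations`` counts ``owl:Class`` typings only.
    """
    g = parse_output(serialization)
    declared = {s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}
    ann = [(s, p, o) for s, p, o in g
           if isinstance(s, URIRef) and isinstance(o, Literal)]
    sub = [(s, o) for s, o in g.subject_objects(RDFS.subClassOf)
           if isinstance(s, URIRef)]
    eq = [(s, o) for s, o in g.subject_objects(OWL.equivalentClass)
          if isinstance(s, URIRef)]
    subjects = declared | {s for s, _p, _o in ann} | {s for s, _o in sub} \
        | {s for s, _o in eq}
    return {
        "classes": len(subjects),
        "declarations": len(declared),
        "annotations": len(ann),
        "superclasses": len(sub),
        "equivalents": len(eq),
    }


def spreadsheet_column_sequence(n: int) -> list[str]:
    """First ``n`` spreadsheet column names by direct enumeration (A, B, ...)."""
    out: list[str] = []
    import itertools
    import string

    for width in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=width):
            out.append("".join(combo))
            if len(out) == n:
                return out
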