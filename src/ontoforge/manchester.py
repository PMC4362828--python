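"""Manchester-OWL-syntax class expressions: parsing, rendering, documents.

The supported construct subset is the one that covers common OBO-style design
patterns: existential (``some``) and universal (``only``) restrictions,
``value`` restrictions, ``and``, ``or``, ``not``, parentheses, and named atoms
written as single-quoted labels, ``<absolute URIs>``, or bare tokens resolved
against the run's URI start portion.  Cardinalities, data ranges, inverse
properties and non-Class frames are deliberately out of contract.

Grammar (precedence low -> high)::

    expression  := conjunction ("or" conjunction)*
    conjunction := unary ("and" unary)*
    unary       := "not" unary | restriction-or-atom
    restriction := termref ("some" | "only") primary
                 | termref "value" termref
    primary     := "not" primary | atom
    atom        := termref | "(" expression ")"
    termref     := 'quoted label' | <URI> | bare-token

Keywords are lower-case reserved words.  Quoted labels use single quotes with
doubled-quote escaping (``'O''Hara cell'``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional, Union

from .errors import LabelResolutionError, ManchesterSyntaxError

KEYWORDS = frozenset({"some", "only", "value", "and", "or", "not"})

_SCHEME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*://")


@dataclass(frozen=True)
class TermRef:
    """A term as written in an expression plus its resolved absolute URI."""

    display: str
    uri: str

    @staticmethod
    def from_label(label: str, uri: str) -> "TermRef":
        return TermRef("'" + label.replace("'", "''") + "'", uri)


@dataclass(frozen=True)
class Named:
    term: TermRef


@dataclass(frozen=True)
class Some:
    property: TermRef
    filler: "ClassExpression"


@dataclass(frozen=True)
class Only:
    property: TermRef
    filler: "ClassExpression"


@dataclass(frozen=True)
class HasValue:
    property: TermRef
    value: TermRef


@dataclass(frozen=True)
class And:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("And requires >= 2 operands")


@dataclass(frozen=True)
class Or:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("Or requires >= 2 operands")


@dataclass(frozen=True)
class Not:
    operand: "ClassExpression"


ClassExpression = Union[Named, Some, Only, HasValue, And, Or, Not]

Resolver = Callable[[str], Optional[str]]


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Tok:
    kind: str  # qlabel | iri | name | kw | lparen | rparen
    value: str
    pos: int


def _lex(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            toks.append(_Tok("lparen", "(", i))
            i += 1
        elif ch == ")":
            toks.append(_Tok("rparen", ")", i))
            i += 1
        elif ch == "'":
            start = i
            i += 1
            parts: list[str] = []
            while True:
                if i >= n:
                    raise ManchesterSyntaxError("unterminated quoted label", start)
                if text[i] == "'":
                    if i + 1 < n and text[i + 1] == "'":  # doubled quote escape
                        parts.append("'")
                        i += 2
                        continue
                    i += 1
                    break
                parts.append(text[i])
                i += 1
            toks.append(_Tok("qlabel", "".join(parts), start))
        elif ch == "<":
            end = text.find(">", i + 1)
            if end == -1:
                raise ManchesterSyntaxError("unterminated <URI>", i)
            toks.append(_Tok("iri", text[i + 1 : end], i))
            i = end + 1
        else:
            start = i
            while i < n and not text[i].isspace() and text[i] not in "()'<>":
                i += 1
            word = text[start:i]
            toks.append(_Tok("kw" if word in KEYWORDS else "name", word, start))
    return toks


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, toks: list[_Tok], text: str, resolver: Resolver,
                 uri_start: str | None):
        self.toks = toks
        self.text = text
        self.i = 0
        self.resolver = resolver
        self.uri_start = uri_start
        self.unknown: list[str] = []

    def peek(self, kind: str, value: str | None = None) -> bool:
        if self.i >= len(self.toks):
            return False
        t = self.toks[self.i]
        return t.kind == kind and (value is None or t.value == value)

    def next(self) -> _Tok:
        t = self.toks[self.i]
        self.i += 1
        return t

    def fail(self, msg: str):
        pos = self.toks[self.i].pos if self.i < len(self.toks) else len(self.text)
        raise ManchesterSyntaxError(msg, pos)

    def term_ref(self) -> TermRef:
        if self.i >= len(self.toks):
            self.fail("expected a term reference")
        t = self.toks[self.i]
        if t.kind == "qlabel":
            self.next()
            uri = self.resolver(t.value)
            if uri is None:
                self.unknown.append(t.value)
                uri = ""
            return TermRef.from_label(t.value, uri)
        if t.kind == "iri":
            self.next()
            if not _SCHEME_RE.match(t.value):
                self.unknown.append(t.value)
            return TermRef("<" + t.value + ">", t.value)
        if t.kind == "name":
            self.next()
            if _SCHEME_RE.match(t.value):
                return TermRef(t.value, t.value)
            if self.uri_start:
                return TermRef(t.value, self.uri_start + t.value)
            self.unknown.append(t.value)
            return TermRef(t.value, "")
        self.fail(f"expected a term reference, found {t.value!r}")

    def parse_expr(self) -> ClassExpression:
        ops = [self.parse_conj()]
        while self.peek("kw", "or"):
            self.next()
            ops.append(self.parse_conj())
        return ops[0] if len(ops) == 1 else Or(tuple(ops))

    def parse_conj(self) -> ClassExpression:
        ops = [self.parse_unary()]
        while self.peek("kw", "and"):
            self.next()
            ops.append(self.parse_unary())
        return ops[0] if len(ops) == 1 else And(tuple(ops))

    def parse_unary(self) -> ClassExpression:
        if self.peek("kw", "not"):
            self.next()
            return Not(self.parse_unary())
        return self.parse_rest()

    def parse_rest(self) -> ClassExpression:
        if self.peek("lparen"):
            self.next()
            e = self.parse_expr()
            if not self.peek("rparen"):
                self.fail("expected ')'")
            self.next()
            return e
        ref = self.term_ref()
        if self.peek("kw", "some") or self.peek("kw", "only"):
            kw = self.next().value
            filler = self.parse_primary()
            return Some(ref, filler) if kw == "some" else Only(ref, filler)
        if self.peek("kw", "value"):
            self.next()
            return HasValue(ref, self.term_ref())
        return Named(ref)

    def parse_primary(self) -> ClassExpression:
        if self.peek("kw", "not"):
            self.next()
            return Not(self.parse_primary())
        if self.peek("lparen"):
            self.next()
            e = self.parse_expr()
            if not self.peek("rparen"):
                self.fail("expected ')'")
            self.next()
            return e
        return Named(self.term_ref())


def parse_class_expression(text: str, resolver: Resolver,
                           uri_start: str | None = None) -> ClassExpression:
    """Parse a fully substituted Manchester class expression.

    ``resolver`` maps a quoted label to its absolute URI (or ``None`` if
    unknown).  Bare tokens that are not absolute URIs are resolved against
    ``uri_start``.  All unresolvable labels are collected and reported
    together in a single :class:`LabelResolutionError`.
    """
    toks = _lex(text)
    if not toks:
        raise ManchesterSyntaxError("empty expression", 0)
    p = _Parser(toks, text, resolver, uri_start)
    expr = p.parse_expr()
    if p.i < len(p.toks):
        p.fail(f"unexpected trailing input {p.toks[p.i].value!r}")
    if p.unknown:
        raise LabelResolutionError(p.unknown)
    return expr


# ---------------------------------------------------------------------------
# Renderer
# ---------------------------------------------------------------------------

def _prec(e: ClassExpression) -> int:
    if isinstance(e, Or):
        return 1
    if isinstance(e, And):
        return 2
    if isinstance(e, Not):
        return 3
    if isinstance(e, (Some, Only, HasValue)):
        return 4
    return 5


def render_class_expression(expr: ClassExpression, *, term_style: str = "display") -> str:
    """Render an expression to minimal-parenthesis canonical text.

    ``term_style`` is ``"display"`` (labels as written) or ``"uri"`` (every
    term as ``<URI>``; used in the intermediate document, which must be
    unambiguous without a label map).  ``parse(render(e))`` is structurally
    equal to ``e``.
    """

    def term(t: TermRef) -> str:
        return "<" + t.uri + ">" if term_style == "uri" else t.display

    def primary(e: ClassExpression) -> str:
        # Restriction fillers admit only atoms; everything else is bracketed.
        if isinstance(e, Named):
            return term(e.term)
        return "(" + r(e) + ")"

    def r(e: ClassExpression) -> str:
        if isinstance(e, Named):
            return term(e.term)
        if isinstance(e, Some):
            return f"{term(e.property)} some {primary(e.filler)}"
        if isinstance(e, Only):
            return f"{term(e.property)} only {primary(e.filler)}"
        if isinstance(e, HasValue):
            return f"{term(e.property)} value {term(e.value)}"
        if isinstance(e, Not):
            inner = r(e.operand)
            return "not " + (inner if _prec(e.operand) >= 3 else "(" + inner + ")")
        if isinstance(e, And):
            return " and ".join(
                r(o) if _prec(o) > 2 else "(" + r(o) + ")" for o in e.operands
            )
        if isinstance(e, Or):
            return " or ".join(
                r(o) if _prec(o) > 1 else "(" + r(o) + ")" for o in e.operands
            )
        raise TypeError(f"not a ClassExpression: {e!r}")

    return r(expr)


# ---------------------------------------------------------------------------
# Intermediate document
# ---------------------------------------------------------------------------

_STD_PREFIXES = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
}


def _literal(value: str, tag: str | None) -> str:
    body = '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if tag is None:
        return body
    if tag.startswith("@"):
        return body + tag
    return body + "^^<" + tag + ">"


def collect_properties(classes) -> tuple[set[str], set[str]]:
    """Return (object property URIs, annotation property URIs) used by classes.

    A term used inside a restriction is an object property; one used in an
    annotation assertion is an annotation property.
    """
    obj: set[str] = set()
    ann: set[str] = set()

    def walk(e: ClassExpression):
        if isinstance(e, (Some, Only)):
            obj.add(e.property.uri)
            walk(e.filler)
        elif isinstance(e, HasValue):
            obj.add(e.property.uri)
        elif isinstance(e, (And, Or)):
            for o in e.operands:
                walk(o)
        elif isinstance(e, Not):
            walk(e.operand)

    for c in classes:
        for (p, _v, _t) in c.annotations:
            ann.add(p)
        for e in list(c.superclasses) + list(c.equivalents):
            walk(e)
    return obj, ann


def render_manchester_document(classes, prefixes=None, *,
                               ontology_iri: str | None = None) -> str:
    """Emit the intermediate OWL 2 Manchester Syntax document.

    One ``Class:`` frame per generated class, with ``Annotations:``,
    ``SubClassOf:`` and ``EquivalentTo:`` entries in that order (one axiom per
    line, so the document is trivially countable by eye when debugging).
    """
    merged = dict(_STD_PREFIXES)
    merged.update(prefixes or {})
    lines = [f"Prefix: {name}: <{uri}>" for name, uri in sorted(merged.items())]
    lines.append("")
    lines.append(f"Ontology: <{ontology_iri}>" if ontology_iri else "Ontology:")
    lines.append("")

    obj_props, ann_props = collect_properties(classes)
    for u in sorted(obj_props):
        lines.append(f"ObjectProperty: <{u}>")
    for u in sorted(ann_props - obj_props):
        lines.append(f"AnnotationProperty: <{u}>")
    if obj_props or ann_props:
        lines.append("")

    for c in classes:
        lines.append(f"Class: <{c.uri}>")
        for (p, v, tag) in c.annotations:
            lines.append(f"    Annotations: <{p}> {_literal(v, tag)}")
        for e in c.superclasses:
            lines.append(
                "    SubClassOf: " + render_class_expression(e, term_style="uri")
            )
        for e in c.equivalents:
            lines.append(
                "    EquivalentTo: " + render_class_expression(e, term_style="uri")
            )
        lines.append("")

    return "\n".join(lines).rstrip("\n") + "\n"
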