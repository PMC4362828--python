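"""The axiom-settings artifact: the reusable, machine-readable pattern file.

A settings file captures everything that makes a design pattern reusable:
which operation to run, the annotation / equivalent-class / superclass
patterns (Manchester syntax with ``{$columnX}`` variables), the label-to-URI
declarations for every quoted term, the URI start portion, and either an ID
policy (new-class generation) or a key column (editing existing classes).

Dialect
-------
Line-oriented UTF-8 text.  Bracketed section headers, one declaration per
line, ``#`` comments, blank lines ignored::

    [Operation]
    new_classes

    [Term ID]
    prefix = VO_
    digits = 7
    start = 10000

    [Start portion of term URI]
    http://purl.obolibrary.org/obo/

    [Term URIs]
    'label' <http://www.w3.org/2000/01/rdf-schema#label>

    [Annotations]
    'label' "{$columnA} cell"

    [Superclasses]
    'is in cell line repository' some 'RIKEN Cell Bank'

Annotation values are double-quoted with doubled-quote escaping and may carry
an optional ``@lang`` or ``^^<datatype URI>`` suffix.  Unknown sections are
warned about and skipped; :func:`serialize_settings` emits sections in a fixed
canonical order so the file diffs cleanly under version control.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .errors import SettingsError
from .manchester import _SCHEME_RE

OP_NEW = "new_classes"
OP_EDIT = "edit_existing"

_SECTIONS = {
    "operation": "Operation",
    "term id": "Term ID",
    "key column": "Key column",
    "start portion of term uri": "Start portion of term URI",
    "multivalue delimiter": "Multivalue delimiter",
    "term uris": "Term URIs",
    "annotations": "Annotations",
    "equivalent classes": "Equivalent classes",
    "superclasses": "Superclasses",
}


@dataclass(frozen=True)
class IdPolicy:
    """Auto-ID policy: ``prefix`` + zero-padded number of ``digits`` digits,
    counting up from ``start``."""

    prefix: str
    digits: int
    start: int

    def __post_init__(self):
        if not self.prefix or any(c.isspace() for c in self.prefix):
            raise ValueError(f"ID prefix must be non-empty, no whitespace: {self.prefix!r}")
        if not 1 <= self.digits <= 18:
            raise ValueError(f"digits must be in 1..18: {self.digits}")
        if not 0 <= self.start < 10 ** self.digits:
            raise ValueError(f"start {self.start} does not fit in {self.digits} digits")


@dataclass
class TermUriMap:
    """Exact-match label -> absolute URI declarations for quoted terms."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for label, uri in self.entries.items():
            if not _SCHEME_RE.match(uri):
                raise ValueError(f"URI for label {label!r} is not absolute: {uri!r}")

    def get(self, label: str) -> str | None:
        return self.entries.get(label)


@dataclass(frozen=True)
class AnnotationPattern:
    """An annotation assertion template: property reference + value template.

    ``property_ref`` is stored in display form: a quoted label (``'label'``)
    or ``<absolute URI>``.  ``tag`` is an optional ``@lang`` or datatype URI.
    """

    property_ref: str
    value_template: str
    tag: str | None = None


@dataclass(frozen=True)
class ExpressionPattern:
    """A Manchester class-expression template; kind is superclass|equivalent."""

    template: str
    kind: str

    def __post_init__(self):
        if self.kind not in ("superclass", "equivalent"):
            raise ValueError(f"bad expression kind: {self.kind!r}")


@dataclass
class AxiomSettings:
    operation: str
    annotation_patterns: list[AnnotationPattern] = field(default_factory=list)
    expression_patterns: list[ExpressionPattern] = field(default_factory=list)
    term_uris: TermUriMap = field(default_factory=TermUriMap)
    uri_start: str = ""
    id_policy: IdPolicy | None = None
    key_column: str | None = None
    multivalue_delimiter: str = "|"

    def check(self):
        """Raise ValueError if the mode-specific invariants do not hold."""
        if self.operation not in (OP_NEW, OP_EDIT):
            raise ValueError(f"bad operation: {self.operation!r}")
        if self.operation == OP_NEW and self.id_policy is None:
            raise ValueError("new_classes requires an ID policy")
        if self.operation == OP_EDIT and not self.key_column:
            raise ValueError("edit_existing requires a key column")
        if len(self.multivalue_delimiter) != 1 or self.multivalue_delimiter in "#\\" \
                or self.multivalue_delimiter.isspace():
            raise ValueError(f"bad multivalue delimiter: {self.multivalue_delimiter!r}")
        if not _SCHEME_RE.match(self.uri_start):
            raise ValueError(f"URI start portion is not absolute: {self.uri_start!r}")


@dataclass(frozen=True)
class Issue:
    kind: str
    message: str


# ---------------------------------------------------------------------------
# Low-level scanning helpers
# ---------------------------------------------------------------------------

def _scan_quoted(text: str, pos: int, quote: str, lineno: int) -> tuple[str, int]:
    """Read a quoted token with doubled-quote escaping; return (value, end)."""
    assert text[pos] == quote
    i = pos + 1
    parts: list[str] = []
    n = len(text)
    while True:
        if i >= n:
            raise SettingsError(f"unterminated {quote}...{quote} token", lineno)
        if text[i] == quote:
            if i + 1 < n and text[i + 1] == quote:
                parts.append(quote)
                i += 2
                continue
            return "".join(parts), i + 1
        parts.append(text[i])
        i += 1


def quote_label(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def quote_value(value: str) -> str:
    return '"' + value.replace('"', '""') + '"'


def _parse_term_ref(line: str, lineno: int) -> tuple[str, int]:
    """Parse a leading quoted label or <URI>; return (display form, end pos)."""
    if line.startswith("'"):
        label, end = _scan_quoted(line, 0, "'", lineno)
        return quote_label(label), end
    if line.startswith("<"):
        close = line.find(">")
        if close == -1:
            raise SettingsError("unterminated <URI>", lineno)
        uri = line[1:close]
        if not _SCHEME_RE.match(uri):
            raise SettingsError(f"URI is not absolute: {uri!r}", lineno)
        return line[: close + 1], close + 1
    raise SettingsError(
        f"expected a quoted label or <URI>, found {line.split()[0]!r}", lineno
    )


_KV_RE = re.compile(r"(\w+)\s*=\s*(\S+)")


# ---------------------------------------------------------------------------
# parse / serialize
# ---------------------------------------------------------------------------

def parse_settings(text: str) -> AxiomSettings:
    """Parse settings-file content into an :class:`AxiomSettings`.

    Comment lines (leading ``#``) and blank lines are ignored; unknown
    sections produce warnings, not errors.  Missing mandatory sections for the
    declared operation, and malformed ID-policy lines, raise
    :class:`SettingsError` with the offending line number where known.
    """
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTIONS:
                warnings.warn(f"line {lineno}: unknown section [{line[1:-1].strip()}] ignored",
                              stacklevel=2)
                current = None
                continue
            current = name
            sections.setdefault(current, [])
            continue
        if current is None:
            warnings.warn(f"line {lineno}: content outside any known section ignored",
                          stacklevel=2)
            continue
        sections[current].append((lineno, line))

    def one_line(name: str) -> tuple[int, str]:
        entries = sections.get(name, [])
        if len(entries) != 1:
            raise SettingsError(
                f"section [{_SECTIONS[name]}] must contain exactly one line",
                entries[1][0] if len(entries) > 1 else None,
            )
        return entries[0]

    if "operation" not in sections:
        raise SettingsError("missing mandatory section [Operation]")
    lineno, op = one_line("operation")
    if op not in (OP_NEW, OP_EDIT):
        raise SettingsError(f"unknown operation {op!r}", lineno)

    for required, mode in (("start portion of term uri", None),
                           ("term id", OP_NEW),
                           ("key column", OP_EDIT)):
        if (mode is None or op == mode) and required not in sections:
            raise SettingsError(
                f"missing mandatory section [{_SECTIONS[required]}] for operation {op}"
            )

    _, uri_start = one_line("start portion of term uri")
    if not _SCHEME_RE.match(uri_start):
        raise SettingsError(f"URI start portion is not absolute: {uri_start!r}")

    id_policy = None
    if "term id" in sections:
        kv: dict[str, str] = {}
        last_lineno = None
        for lineno, line in sections["term id"]:
            last_lineno = lineno
            matches = list(_KV_RE.finditer(line))
            joined = re.sub(r"\s+", "", "".join(m.group(0) for m in matches))
            if not matches or joined != re.sub(r"\s+", "", line):
                raise SettingsError(f"malformed ID policy line: {line!r}", lineno)
            for m in matches:
                kv[m.group(1).lower()] = m.group(2)
        try:
            id_policy = IdPolicy(
                prefix=kv["prefix"],
                digits=int(kv["digits"]),
                start=int(kv.get("start", "1")),
            )
        except KeyError as exc:
            raise SettingsError(f"ID policy is missing {exc.args[0]!r}", last_lineno)
        except ValueError as exc:
            raise SettingsError(f"malformed ID policy: {exc}", last_lineno)

    key_column = None
    if "key column" in sections:
        lineno, line = one_line("key column")
        if not (line.isalpha() and line.isascii()):
            raise SettingsError(f"key column must be column letters: {line!r}", lineno)
        key_column = line.upper()

    delimiter = "|"
    if "multivalue delimiter" in sections:
        lineno, line = one_line("multivalue delimiter")
        if len(line) != 1 or line in "#\\":
            raise SettingsError(f"multivalue delimiter must be a single character: {line!r}",
                                lineno)
        delimiter = line

    term_uris: dict[str, str] = {}
    for lineno, line in sections.get("term uris", []):
        if not line.startswith("'"):
            raise SettingsError("term-URI line must start with a quoted label", lineno)
        label, end = _scan_quoted(line, 0, "'", lineno)
        rest = line[end:].strip()
        if not (rest.startswith("<") and rest.endswith(">")):
            raise SettingsError(f"expected <URI> after label {label!r}", lineno)
        uri = rest[1:-1]
        if not _SCHEME_RE.match(uri):
            raise SettingsError(f"URI is not absolute: {uri!r}", lineno)
        if label in term_uris:
            raise SettingsError(f"duplicate term-URI declaration for {label!r}", lineno)
        term_uris[label] = uri

    annotation_patterns: list[AnnotationPattern] = []
    for lineno, line in sections.get("annotations", []):
        ref, end = _parse_term_ref(line, lineno)
        rest = line[end:].strip()
        if not rest.startswith('"'):
            raise SettingsError('expected a double-quoted value template', lineno)
        value, vend = _scan_quoted(rest, 0, '"', lineno)
        suffix = rest[vend:].strip()
        tag: str | None = None
        if suffix:
            if suffix.startswith("@") and len(suffix) > 1:
                tag = suffix
            elif suffix.startswith("^^<") and suffix.endswith(">"):
                tag = suffix[3:-1]
            else:
                raise SettingsError(f"bad annotation suffix: {suffix!r}", lineno)
        annotation_patterns.append(AnnotationPattern(ref, value, tag))

    expression_patterns: list[ExpressionPattern] = []
    for section, kind in (("equivalent classes", "equivalent"),
                          ("superclasses", "superclass")):
        for _lineno, line in sections.get(section, []):
            expression_patterns.append(ExpressionPattern(line, kind))

    settings = AxiomSettings(
        operation=op,
        annotation_patterns=annotation_patterns,
        expression_patterns=expression_patterns,
        term_uris=TermUriMap(term_uris),
        uri_start=uri_start,
        id_policy=id_policy,
        key_column=key_column,
        multivalue_delimiter=delimiter,
    )
    return settings


def serialize_settings(settings: AxiomSettings) -> str:
    """Serialize to canonical settings-file text; ``parse(serialize(s)) == s``.

    Section order is fixed: Operation, Term ID, Key column, Start portion of
    term URI, Multivalue delimiter, Term URIs, Annotations, Equivalent
    classes, Superclasses.  Sections with no content are omitted.
    """
    settings.check()
    out: list[str] = ["[Operation]", settings.operation, ""]
    if settings.id_policy is not None:
        p = settings.id_policy
        out += ["[Term ID]", f"prefix = {p.prefix}", f"digits = {p.digits}",
                f"start = {p.start}", ""]
    if settings.key_column:
        out += ["[Key column]", settings.key_column, ""]
    out += ["[Start portion of term URI]", settings.uri_start, ""]
    out += ["[Multivalue delimiter]", settings.multivalue_delimiter, ""]
    if settings.term_uris.entries:
        out.append("[Term URIs]")
        out += [f"{quote_label(l)} <{u}>" for l, u in settings.term_uris.entries.items()]
        out.append("")
    if settings.annotation_patterns:
        out.append("[Annotations]")
        for pat in settings.annotation_patterns:
            suffix = ""
            if pat.tag is not None:
                suffix = pat.tag if pat.tag.startswith("@") else f"^^<{pat.tag}>"
            out.append(f"{pat.property_ref} {quote_value(pat.value_template)}{suffix}")
        out.append("")
    for kind, header in (("equivalent", "Equivalent classes"),
                         ("superclass", "Superclasses")):
        pats = [p for p in settings.expression_patterns if p.kind == kind]
        if pats:
            out.append(f"[{header}]")
            out += [p.template for p in pats]
            out.append("")
    return "\n".join(out).rstrip("\n") + "\n"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _capacity(policy: IdPolicy, used: set[int] | None = None) -> int:
    cap = 10 ** policy.digits - policy.start
    if used:
        cap -= len({u for u in used if u >= policy.start})
    return cap


def validate_settings(settings: AxiomSettings, table, snapshot=None) -> list[Issue]:
    """Check a (settings, table) pair; an empty result means the run can proceed.

    All problems are returned as :class:`Issue` values, never raised: unknown
    quoted labels, variables addressing columns beyond the table, exhausted ID
    capacity, a missing key column in edit mode, unparseable expression
    templates, and terms used both as annotation and object properties.
    When a target-ontology ``snapshot`` is given, its label index extends the
    known labels and its scanned IDs reduce the available capacity — exactly
    as the engine itself will behave.
    """
    from . import template_engine as te  # local import to avoid a cycle
    from . import manchester as ms

    issues: list[Issue] = []
    seen: set[tuple[str, str]] = set()

    def add(kind: str, message: str):
        key = (kind, message)
        if key not in seen:
            seen.add(key)
            issues.append(Issue(kind, message))

    known = dict(snapshot.label_index) if snapshot is not None else {}
    known.update(settings.term_uris.entries)

    def resolver(label: str):
        return known.get(label)

    def probe_resolver(label: str):
        return known.get(label, "http://example.invalid/probe")

    width = table.width
    n_rows = len(table.rows)

    def check_columns(template: str, context: str):
        if n_rows == 0:
            return  # nothing will be emitted, so no cell can be missing
        for letters in te.find_variables(template):
            from .datatable import column_index
            if column_index(letters) >= width:
                add("out_of_range_column",
                    f"{context} references {{$column{letters}}} but the table has "
                    f"only {width} column(s)")

    ann_prop_uris: set[str] = set()
    obj_prop_uris: set[str] = set()

    for pat in settings.annotation_patterns:
        check_columns(pat.value_template, f"annotation pattern {pat.value_template!r}")
        if pat.property_ref.startswith("'"):
            label = te.unquote_label(pat.property_ref)
            uri = known.get(label)
            if uri is None:
                add("unknown_label",
                    f"annotation property label {label!r} is not declared in [Term URIs]")
            else:
                ann_prop_uris.add(uri)
        else:
            ann_prop_uris.add(pat.property_ref[1:-1])

    for pat in settings.expression_patterns:
        check_columns(pat.template, f"{pat.kind} pattern {pat.template!r}")
        probe = te.substitute_values(
            pat.template,
            {c: "'__probe__'" for c in te.find_variables(pat.template)},
        )
        try:
            expr = ms.parse_class_expression(probe, probe_resolver,
                                             uri_start=settings.uri_start or None)
        except ms.ManchesterSyntaxError as exc:
            add("template_syntax", f"{pat.kind} pattern {pat.template!r}: {exc}")
            continue
        except Exception as exc:  # pragma: no cover - defensive
            add("template_syntax", f"{pat.kind} pattern {pat.template!r}: {exc}")
            continue
        obj, _ = ms.collect_properties([_ProbeClass(expr, pat.kind)])
        obj_prop_uris |= obj
        # Labels written literally in the template must be declared.
        for label in _quoted_labels(probe):
            if label != "__probe__" and label not in known:
                add("unknown_label",
                    f"label {label!r} in {pat.kind} pattern is not declared in [Term URIs]")
        # Exercise the actual rows: cells may themselves carry labels/URIs.
        for row in range(n_rows):
            cols = te.find_variables(pat.template)
            vals = [te.dt.cell(table, row, c) for c in cols]
            if any(v == "" for v in vals):
                continue  # skipped by the empty-cell rule; nothing to resolve
            for combo_vals in te.multivalue_combinations(vals, settings.multivalue_delimiter):
                text = te.substitute_values(pat.template, dict(zip(cols, combo_vals)))
                try:
                    ms.parse_class_expression(text, resolver,
                                              uri_start=settings.uri_start or None)
                except ms.LabelResolutionError as exc:
                    for label in exc.labels:
                        add("unknown_label",
                            f"label {label!r} (row {row}, {pat.kind} pattern) "
                            f"cannot be resolved")
                except ms.ManchesterSyntaxError as exc:
                    add("template_syntax",
                        f"{pat.kind} pattern at row {row}: {exc}")

    conflict = ann_prop_uris & obj_prop_uris
    for uri in sorted(conflict):
        add("property_role_conflict",
            f"term <{uri}> is used both as an annotation property and inside a "
            f"class expression")

    if settings.operation == OP_EDIT:
        if not settings.key_column:
            add("missing_key_column", "edit_existing operation requires a key column")
        else:
            from .datatable import column_index
            if column_index(settings.key_column) >= width:
                add("out_of_range_column",
                    f"key column {settings.key_column} is beyond the table width {width}")

    if settings.operation == OP_NEW and settings.id_policy is not None:
        used = set()
        if snapshot is not None:
            from .id_allocator import scan_existing_ids
            used = scan_existing_ids(snapshot, settings.id_policy, settings.uri_start)
        needed = sum(1 for r in table.rows if any(c != "" for c in r))
        cap = _capacity(settings.id_policy, used)
        if needed > cap:
            add("id_capacity",
                f"{needed} IDs needed but only {cap} available under policy "
                f"{settings.id_policy.prefix}/{settings.id_policy.digits} digits "
                f"from {settings.id_policy.start}")

    return issues


class _ProbeClass:
    """Minimal stand-in with the GeneratedClass shape for property collection."""

    def __init__(self, expr, kind):
        self.annotations = []
        self.superclasses = [expr] if kind == "superclass" else []
        self.equivalents = [expr] if kind == "equivalent" else []
        self.uri = "http://example.invalid/probe-subject"


def _quoted_labels(text: str) -> list[str]:
    from .manchester import _lex
    try:
        return [t.value for t in _lex(text) if t.kind == "qlabel"]
    except Exception:
        return []
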