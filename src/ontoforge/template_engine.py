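"""Row-wise instantiation of axiom patterns: the ``{$columnX}`` convention.

Each data row fills the variables of every pattern.  Patterns whose referenced
cells are all non-empty yield axioms; a pattern touching any empty cell is
dropped for that row (emitting axioms with blank literals or dangling
expressions would corrupt an ontology) and the skip is recorded.  Multi-valued
cells — values separated by the settings' delimiter, backslash-escapable —
expand to one axiom per value, Cartesian-product style when one pattern
references several multi-valued cells.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

from . import datatable as dt
from .errors import RowError
from .manchester import (
    ClassExpression,
    LabelResolutionError,
    ManchesterSyntaxError,
    _SCHEME_RE,
    parse_class_expression,
)
from .settings import OP_NEW, AxiomSettings

VARIABLE_RE = re.compile(r"\{\$column([A-Za-z]+)\}")

#: above this many Cartesian combinations per pattern a warning is issued
COMBINATION_WARN_LIMIT = 25


@dataclass
class SubstitutionResult:
    text: str
    all_filled: bool
    used_columns: list[str]


@dataclass
class GeneratedClass:
    """One output term: URI, annotation assertions, and class axioms.

    ``annotations`` holds ``(property URI, literal value, tag)`` triples where
    ``tag`` is ``None``, an ``@lang`` string, or a datatype URI.  ``is_new``
    is False in edit-existing mode: axioms only, no declaration.
    """

    uri: str
    annotations: list[tuple[str, str, str | None]] = field(default_factory=list)
    superclasses: list[ClassExpression] = field(default_factory=list)
    equivalents: list[ClassExpression] = field(default_factory=list)
    is_new: bool = True


def find_variables(template: str) -> list[str]:
    """Column letters referenced by a template, unique, first-occurrence order.

    Only the exact token shape ``{$column<LETTERS>}`` matches; near-misses
    like ``{$colA}`` or ``{$column1}`` are left untouched and warned about.
    """
    seen: list[str] = []
    for m in VARIABLE_RE.finditer(template):
        letters = m.group(1).upper()
        if letters not in seen:
            seen.append(letters)
    for m in re.finditer(r"\{\$", template):
        if not VARIABLE_RE.match(template, m.start()):
            snippet = template[m.start() : m.start() + 12]
            warnings.warn(
                f"malformed variable near {snippet!r} ignored "
                f"(expected {{$column<LETTERS>}})",
                stacklevel=2,
            )
    return seen


def substitute_values(template: str, values: dict[str, str]) -> str:
    """Replace each ``{$columnX}`` with ``values[X]`` (letters upper-cased)."""
    return VARIABLE_RE.sub(lambda m: values.get(m.group(1).upper(), ""), template)


def substitute(template: str, table: dt.DataTable, row: int) -> SubstitutionResult:
    """Substitute row cells into a template.

    ``all_filled`` is True iff every referenced cell is non-empty and no
    malformed variable residue remains in the output.
    """
    cols = find_variables(template)
    values = {c: dt.cell(table, row, c) for c in cols}
    text = substitute_values(template, values)
    all_filled = all(v != "" for v in values.values()) and "{$column" not in text
    return SubstitutionResult(text, all_filled, cols)


def split_multivalue(text: str, delimiter: str) -> list[str]:
    """Split a cell on the delimiter; ``\\<delimiter>`` escapes a literal one."""
    parts: list[str] = []
    buf: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\\" and i + 1 < n and text[i + 1] == delimiter:
            buf.append(delimiter)
            i += 2
        elif ch == delimiter:
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    parts.append("".join(buf))
    return parts


def multivalue_combinations(values: list[str], delimiter: str):
    """Cartesian product of the multi-value splits of each cell value."""
    return itertools.product(*(split_multivalue(v, delimiter) for v in values))


def _resolve_property_ref(ref: str, resolver, uri_start: str | None) -> str:
    from .settings import _scan_quoted

    if ref.startswith("<") and ref.endswith(">"):
        return ref[1:-1]
    if ref.startswith("'"):
        label, _ = _scan_quoted(ref, 0, "'", 0)
        uri = resolver(label)
        if uri is None:
            raise LabelResolutionError([label])
        return uri
    if _SCHEME_RE.match(ref):
        return ref
    if uri_start:
        return uri_start + ref
    raise LabelResolutionError([ref])


def unquote_label(ref: str) -> str:
    from .settings import _scan_quoted

    label, _ = _scan_quoted(ref, 0, "'", 0)
    return label


def expand_row(
    settings: AxiomSettings,
    table: dt.DataTable,
    row: int,
    subject_uri: str,
    resolver,
    *,
    skipped: list | None = None,
    warn_list: list | None = None,
) -> GeneratedClass:
    """Assemble one :class:`GeneratedClass` from a data row.

    Patterns with any empty referenced cell are skipped and recorded in
    ``skipped`` as ``(row, pattern, reason)``.  A substituted expression that
    fails to parse raises :class:`RowError` carrying the row number, the
    pattern, and the parser message.
    """
    delim = settings.multivalue_delimiter
    gc = GeneratedClass(uri=subject_uri, is_new=settings.operation == OP_NEW)

    def record_skip(pattern: str, reason: str):
        if skipped is not None:
            skipped.append((row, pattern, reason))

    def combos_for(template: str, pattern_repr: str):
        cols = find_variables(template)
        vals = [dt.cell(table, row, c) for c in cols]
        empty = [c for c, v in zip(cols, vals) if v == ""]
        if empty:
            record_skip(pattern_repr,
                        "empty cell in column " + ", ".join(empty))
            return cols, None
        combos = list(multivalue_combinations(vals, delim))
        if len(combos) > COMBINATION_WARN_LIMIT and warn_list is not None:
            warn_list.append(
                f"row {row}: pattern {pattern_repr!r} expands to "
                f"{len(combos)} combinations"
            )
        return cols, combos

    for pat in settings.annotation_patterns:
        cols, combos = combos_for(pat.value_template, pat.value_template)
        if combos is None:
            continue
        try:
            prop_uri = _resolve_property_ref(pat.property_ref, resolver,
                                             settings.uri_start or None)
        except LabelResolutionError as exc:
            raise RowError(row, pat.property_ref, str(exc)) from exc
        for combo in combos:
            value = substitute_values(pat.value_template, dict(zip(cols, combo)))
            entry = (prop_uri, value, pat.tag)
            if entry not in gc.annotations:  # OWL axioms are set-valued
                gc.annotations.append(entry)

    for pat in settings.expression_patterns:
        cols, combos = combos_for(pat.template, pat.template)
        if combos is None:
            continue
        target = gc.superclasses if pat.kind == "superclass" else gc.equivalents
        for combo in combos:
            text = substitute_values(pat.template, dict(zip(cols, combo)))
            try:
                expr = parse_class_expression(text, resolver,
                                              uri_start=settings.uri_start or None)
            except (ManchesterSyntaxError, LabelResolutionError) as exc:
                raise RowError(row, pat.template, str(exc)) from exc
            if expr not in target:  # duplicate axioms are meaningless in OWL
                target.append(expr)

    return gc
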