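"""Synthetic test inputs, generated in memory — no downloads, ever.

The cell-line bundle reconstructs the published worked example from its
printed fragments (the ``RCB2320`` row, the repository superclass pattern,
the ``"{$columnA} cell"`` label pattern); URIs and cell values that were
never printed as text are clearly synthetic placeholders.  The expectation
counts attached to every bundle are computed here by direct enumeration over
patterns × rows × the empty-cell / multi-value rules, sharing no code with
the engine, so they can serve as an independent oracle in tests.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .datatable import DataTable
from .settings import IdPolicy

OBO = "http://purl.obolibrary.org/obo/"

# -- independent enumeration helpers (deliberately not imported from the
#    engine modules; see module docstring) ----------------------------------

_VAR = re.compile(r"\{\$column([A-Za-z]+)\}")


def _col(letters: str) -> int:
    n = 0
    for ch in letters.upper():
        n = n * 26 + ord(ch) - ord("A") + 1
    return n - 1


def _split(text: str, delim: str) -> list[str]:
    out, buf = [], ""
    i = 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text) and text[i + 1] == delim:
            buf += delim
            i += 2
        elif text[i] == delim:
            out.append(buf)
            buf = ""
            i += 1
        else:
            buf += text[i]
            i += 1
    out.append(buf)
    return out


def _instances(template: str, row: list[str], delim: str) -> set[str]:
    """All distinct substituted texts a pattern yields for a row (empty set
    when any referenced cell is empty — the skip rule)."""
    import itertools

    letters = list(dict.fromkeys(m.upper() for m in _VAR.findall(template)))
    splits = []
    for ls in letters:
        idx = _col(ls)
        val = row[idx] if idx < len(row) else ""
        if val == "":
            return set()
        splits.append(_split(val, delim))
    out: set[str] = set()
    for combo in itertools.product(*splits):
        mapping = dict(zip(letters, combo))
        out.add(_VAR.sub(lambda m: mapping[m.group(1).upper()], template))
    return out


@dataclass
class Expectations:
    """Axiom counts enumerated directly from patterns x rows x rules."""

    classes: int = 0
    annotations: int = 0
    superclasses: int = 0
    equivalents: int = 0


@dataclass
class FixtureBundle:
    settings_text: str
    table: DataTable
    target_ontology_text: str | None
    expectations: Expectations


def _enumerate(rows, ann_patterns, sup_templates, eq_templates, delim,
               new_classes=True) -> Expectations:
    """Count axioms per the skip / multi-value / set-semantics rules.

    ``ann_patterns`` is a list of (property reference, value template) pairs;
    duplicates within a class collapse, as axioms are set-valued.
    """
    exp = Expectations()
    for row in rows:
        if all(c == "" for c in row):
            continue
        if new_classes:
            exp.classes += 1
        ann: set[tuple[str, str]] = set()
        for ref, t in ann_patterns:
            ann |= {(ref, v) for v in _instances(t, row, delim)}
        sup: set[str] = set()
        for t in sup_templates:
            sup |= _instances(t, row, delim)
        eq: set[str] = set()
        for t in eq_templates:
            eq |= _instances(t, row, delim)
        exp.annotations += len(ann)
        exp.superclasses += len(sup)
        exp.equivalents += len(eq)
    return exp


# ---------------------------------------------------------------------------
# Cell-line bundle (worked example reconstructed from printed fragments)
# ---------------------------------------------------------------------------

CLO_REPOSITORY_PROPERTY_URI = OBO + "CLO_9000001"  # synthetic placeholder URI
CLO_RIKEN_BANK_URI = OBO + "CLO_9000002"           # synthetic placeholder URI

_CLO_SETTINGS = f"""\
# Cell-line cell design pattern: one new class per repository catalogue row.
[Operation]
new_classes

[Term ID]
prefix = CLO_
digits = 7
start = 10000

[Start portion of term URI]
{OBO}

[Term URIs]
'label' <http://www.w3.org/2000/01/rdf-schema#label>
'comment' <http://www.w3.org/2000/01/rdf-schema#comment>
'is in cell line repository' <{CLO_REPOSITORY_PROPERTY_URI}>
'RIKEN Cell Bank' <{CLO_RIKEN_BANK_URI}>

[Annotations]
'label' "{{$columnA}} cell"
'comment' "Derived from tissue: {{$columnG}} in animal: {{$columnF}}."

[Superclasses]
'is in cell line repository' some 'RIKEN Cell Bank'
"""

_CLO_HEADER = ["catalogue ID", "originator", "register", "year", "notes",
               "animal", "tissue"]

# Row 0 column A is the printed catalogue number; everything else synthetic.
_CLO_ROWS = [
    ["RCB2320", "originator-1", "register-1", "1991", "synthetic note 1",
     "Mus musculus", "liver"],
    ["RCB9001", "originator-2", "register-2", "1994", "synthetic note 2",
     "Mus musculus", "kidney"],
    ["RCB9002", "originator-3", "register-1", "2002", "synthetic note 3",
     "Homo sapiens", "skin"],
]


def make_clo_fixture() -> FixtureBundle:
    """Cell-line bundle: 3 rows, label/comment annotations, one superclass."""
    table = DataTable(header=list(_CLO_HEADER), rows=[list(r) for r in _CLO_ROWS])
    exp = _enumerate(
        table.rows,
        ann_patterns=[("'label'", "{$columnA} cell"),
                      ("'comment'",
                       "Derived from tissue: {$columnG} in animal: {$columnF}.")],
        sup_templates=["'is in cell line repository' some 'RIKEN Cell Bank'"],
        eq_templates=[],
        delim="|",
    )
    return FixtureBundle(_CLO_SETTINGS, table, None, exp)


# ---------------------------------------------------------------------------
# Biobank-style edit-existing bundle
# ---------------------------------------------------------------------------

DEFINITION_EDITOR_URI = OBO + "IAO_9000111"  # synthetic placeholder URI
DEFINITION_SOURCE_URI = OBO + "IAO_9000119"  # synthetic placeholder URI

_BIOBANK_SETTINGS = f"""\
# Add definition-editor and definition-source annotations to existing classes.
[Operation]
edit_existing

[Key column]
A

[Start portion of term URI]
{OBO}

[Term URIs]
'definition editor' <{DEFINITION_EDITOR_URI}>
'definition source' <{DEFINITION_SOURCE_URI}>

[Annotations]
'definition editor' "{{$columnC}}"
'definition source' "{{$columnD}}"
"""


def make_biobank_fixture(rows: int, empty_source_rows=()) -> FixtureBundle:
    """Edit-existing bundle: key URIs in column A, two annotation patterns.

    ``empty_source_rows`` lists row indices whose column D is left blank so
    the empty-cell skip rule can be exercised.
    """
    if rows < 1:
        raise ValueError("rows must be >= 1")
    empty = set(empty_source_rows)
    grid = []
    for i in range(rows):
        grid.append([
            f"{OBO}BIOBANK_{9000000 + i:07d}",
            f"biobank term {i}",
            f"Editor {i % 3 + 1}",
            "" if i in empty else f"SOURCE:{900000 + i}",
        ])
    table = DataTable(header=["term URI", "label", "editor", "source"], rows=grid)
    exp = _enumerate(table.rows,
                     ann_patterns=[("'definition editor'", "{$columnC}"),
                                   ("'definition source'", "{$columnD}")],
                     sup_templates=[], eq_templates=[], delim="|",
                     new_classes=False)
    return FixtureBundle(_BIOBANK_SETTINGS, table, None, exp)


# ---------------------------------------------------------------------------
# Randomized bundles
# ---------------------------------------------------------------------------

_TERM_POOL = [f"term {i}" for i in range(1, 7)]
_REL_POOL = [f"relation {i}" for i in range(1, 4)]
_ANN_POOL = ["note alpha", "note beta", "note gamma"]
_WORDS = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]


def _term_uri_block() -> str:
    lines = []
    for i, label in enumerate(_TERM_POOL, start=1):
        lines.append(f"'{label}' <{OBO}EX_{9100000 + i:07d}>")
    for i, label in enumerate(_REL_POOL, start=1):
        lines.append(f"'{label}' <{OBO}EX_{9200000 + i:07d}>")
    for i, label in enumerate(_ANN_POOL, start=1):
        lines.append(f"'{label}' <{OBO}EX_{9300000 + i:07d}>")
    return "\n".join(lines)


def make_random_bundle(seed: int, rows: int = 8, patterns: int = 4,
                       empty_rate: float = 0.2) -> FixtureBundle:
    """Deterministic randomized new-classes bundle.

    Column A (an item name) is never blanked, so every row yields a class;
    columns B/C carry annotation values (sometimes multi-valued), columns D/E
    carry quoted term labels for expression patterns.  Pattern-referenced
    cells are blanked independently at ``empty_rate``.
    """
    if rows < 1 or patterns < 1 or not 0.0 <= empty_rate <= 1.0:
        raise ValueError("parameters out of range")
    rng = random.Random(seed)

    n_ann = max(1, patterns // 2)
    n_expr = patterns - n_ann
    ann_pairs = []
    for _ in range(n_ann):
        ann_pairs.append((
            f"'{rng.choice(_ANN_POOL)}'",
            rng.choice(["{$columnB} unit", "{$columnC}",
                        "{$columnB} of {$columnC}"]),
        ))
    sup_templates, eq_templates = [], []
    for _ in range(n_expr):
        rel = rng.choice(_REL_POOL)
        rel2 = rng.choice(_REL_POOL)
        t = rng.choice(_TERM_POOL)
        template = rng.choice([
            f"'{rel}' some {{$columnD}}",
            f"'{rel}' only {{$columnD}}",
            f"'{rel}' some ({{$columnE}} and '{rel2}' some '{t}')",
            f"'{rel}' some (not {{$columnD}})",
            f"{{$columnE}} or '{t}'",
        ])
        (sup_templates if rng.random() < 0.7 else eq_templates).append(template)

    def maybe_blank(value: str) -> str:
        return "" if rng.random() < empty_rate else value

    def ann_cell() -> str:
        if rng.random() < 0.25:
            return rng.choice(_WORDS) + "|" + rng.choice(_WORDS)
        return rng.choice(_WORDS)

    def expr_cell() -> str:
        if rng.random() < 0.25:
            return f"'{rng.choice(_TERM_POOL)}'|'{rng.choice(_TERM_POOL)}'"
        return f"'{rng.choice(_TERM_POOL)}'"

    grid = []
    for i in range(rows):
        grid.append([
            f"item-{i}",
            maybe_blank(ann_cell()),
            maybe_blank(ann_cell()),
            maybe_blank(expr_cell()),
            maybe_blank(expr_cell()),
        ])
    table = DataTable(header=["name", "value1", "value2", "filler1", "filler2"],
                      rows=grid)

    ann_lines = "\n".join(f'{ref} "{t}"' for ref, t in ann_pairs)
    sup_block = ("\n[Superclasses]\n" + "\n".join(sup_templates) + "\n"
                 if sup_templates else "")
    eq_block = ("\n[Equivalent classes]\n" + "\n".join(eq_templates) + "\n"
                if eq_templates else "")
    settings_text = f"""\
[Operation]
new_classes

[Term ID]
prefix = EX_
digits = 7
start = 1000

[Start portion of term URI]
{OBO}

[Term URIs]
{_term_uri_block()}

[Annotations]
{ann_lines}
{eq_block}{sup_block}"""

    exp = _enumerate(table.rows, ann_pairs, sup_templates, eq_templates,
                     delim="|")
    return FixtureBundle(settings_text, table, None, exp)


def make_target_ontology(existing_ids, policy: IdPolicy, uri_start: str) -> str:
    """RDF/XML ontology declaring one class per ID (deduplicated) with labels."""
    for i in existing_ids:
        if not 0 <= i < 10 ** policy.digits:
            raise ValueError(f"ID {i} does not fit the policy digit width")
    g = Graph()
    iri = URIRef(uri_start + "synthetic-target.owl")
    g.add((iri, RDF.type, OWL.Ontology))
    for i in sorted(set(existing_ids)):
        u = URIRef(uri_start + policy.prefix + str(i).zfill(policy.digits))
        g.add((u, RDF.type, OWL.Class))
        g.add((u, RDFS.label, Literal(f"existing term {i}")))
    return g.serialize(format="pretty-xml")


# ---------------------------------------------------------------------------
# Random AxiomSettings / expression trees (round-trip property material)
# ---------------------------------------------------------------------------

def make_random_settings(seed: int):
    """A randomized but invariant-satisfying AxiomSettings object."""
    from .manchester import render_class_expression
    from .settings import (AnnotationPattern, AxiomSettings, ExpressionPattern,
                           TermUriMap)

    rng = random.Random(seed)
    labels = ["plain label", "O''s label".replace("''", "'"), "label two",
              "sp3ci@l (label)", "with  double  spaces"]
    rng.shuffle(labels)
    n_terms = rng.randint(1, len(labels))
    term_uris = {labels[i]: f"{OBO}RT_{9000000 + i:07d}" for i in range(n_terms)}

    uri_by_label = dict(term_uris)

    def random_tree(depth: int):
        exprs = list(uri_by_label)
        if depth <= 0 or rng.random() < 0.4:
            label = rng.choice(exprs)
            from .manchester import Named, TermRef
            return Named(TermRef.from_label(label, uri_by_label[label]))
        from .manchester import And, HasValue, Named, Not, Only, Or, Some, TermRef

        kind = rng.choice(["some", "only", "value", "and", "or", "not"])
        prop = rng.choice(exprs)
        ref = TermRef.from_label(prop, uri_by_label[prop])
        if kind == "some":
            return Some(ref, random_tree(depth - 1))
        if kind == "only":
            return Only(ref, random_tree(depth - 1))
        if kind == "value":
            val = rng.choice(exprs)
            return HasValue(ref, TermRef.from_label(val, uri_by_label[val]))
        if kind == "not":
            return Not(random_tree(depth - 1))
        ops = tuple(random_tree(depth - 1) for _ in range(rng.randint(2, 3)))
        return And(ops) if kind == "and" else Or(ops)

    operation = rng.choice(["new_classes", "edit_existing"])
    ann_patterns = []
    for _ in range(rng.randint(0, 3)):
        if rng.random() < 0.5 and term_uris:
            ref = "'" + rng.choice(list(term_uris)).replace("'", "''") + "'"
        else:
            ref = f"<{OBO}RT_{rng.randint(9100000, 9199999):07d}>"
        value = rng.choice([
            "{$columnA} thing", 'quote "inside" here', "plain",
            "{$columnB}|not-a-delimiter", "trailing space ",
        ])
        tag = rng.choice([None, "@en", "http://www.w3.org/2001/XMLSchema#string"])
        ann_patterns.append(AnnotationPattern(ref, value, tag))
    expr_patterns = []
    for _ in range(rng.randint(0, 3)):
        tree = random_tree(rng.randint(0, 2))
        expr_patterns.append(
            ExpressionPattern(render_class_expression(tree),
                              rng.choice(["superclass", "equivalent"]))
        )
    # canonical file order groups equivalents before superclasses
    expr_patterns.sort(key=lambda p: p.kind)

    return AxiomSettings(
        operation=operation,
        annotation_patterns=ann_patterns,
        expression_patterns=expr_patterns,
        term_uris=TermUriMap(term_uris),
        uri_start=OBO,
        id_policy=(IdPolicy(rng.choice(["RT_", "X_"]), rng.randint(2, 9),
                            rng.randint(0, 50))
                   if operation == "new_classes" else None),
        key_column=("A" if operation == "edit_existing" else None),
        multivalue_delimiter=rng.choice(["|", ";", ","]),
    )


def random_class_expression(rng: random.Random, max_depth: int = 4):
    """A random expression tree over a small resolved vocabulary.

    Returns ``(expr, resolver)`` where ``resolver`` knows every label used,
    so ``parse(render(expr), resolver)`` is well defined.
    """
    from .manchester import And, HasValue, Named, Not, Only, Or, Some, TermRef

    vocab = {f"concept {i}": f"{OBO}RC_{9400000 + i:07d}" for i in range(1, 8)}
    vocab.update({f"link {i}": f"{OBO}RC_{9500000 + i:07d}" for i in range(1, 4)})
    labels = list(vocab)

    def ref() -> TermRef:
        label = rng.choice(labels)
        return TermRef.from_label(label, vocab[label])

    def build(depth: int):
        if depth <= 0 or rng.random() < 0.35:
            return Named(ref())
        kind = rng.choice(["some", "only", "value", "and", "or", "not"])
        if kind == "some":
            return Some(ref(), build(depth - 1))
        if kind == "only":
            return Only(ref(), build(depth - 1))
        if kind == "value":
            return HasValue(ref(), ref())
        if kind == "not":
            return Not(build(depth - 1))
        ops = tuple(build(depth - 1) for _ in range(rng.randint(2, 3)))
        return And(ops) if kind == "and" else Or(ops)

    return build(max_depth), vocab.get
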