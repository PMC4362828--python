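# Methods

This note records the model behind ontoforge, the defaults that matter, the
design choices made where the design was genuinely open, and what the test
fixtures do and do not establish about real ontology-building runs.

## The expansion model

A run is a pure function of three inputs: an `AxiomSettings` value (the
pattern), a `DataTable` (the populated template), and an optional
`OntologySnapshot` (the target ontology).  For every data row the engine
instantiates each pattern by textual substitution of `{$columnX}` variables
with that row's cells, then interprets the result: annotation templates
become `(annotation property, literal)` assertions; expression templates are
parsed as Manchester-syntax class expressions and become subclass or
equivalence axioms.  Substitution happens *before* parsing, so a cell may
itself contribute structure — a quoted label, a `<URI>`, or a bare local ID
— to the expression.  Column letters always address data rows; the header
row, when present, is descriptive only.

Three rules govern the row-to-axiom mapping:

* **Empty-cell rule.** A pattern whose substitution touches any empty
  referenced cell is dropped for that row and recorded in the run report.
  Emitting an axiom with a blank literal or a dangling operand would corrupt
  the ontology; silently emitting nothing without a record would hide data
  problems.  Rows that are entirely empty are skipped.
* **Multi-value rule.** A cell may carry several values separated by the
  settings' delimiter (default `|`, escapable as `\|`; the delimiter is a
  settings-level choice because spreadsheet conventions differ).  A pattern
  referencing k multi-valued cells expands to the Cartesian product of the
  splits — predictable semantics for a case with no single obvious answer —
  and a run-report warning is issued above 25 combinations per pattern.
* **Set semantics.** Axioms attached to one class are a set: duplicate
  instantiations (e.g. a cell `a|a`, or two patterns collapsing to the same
  assertion) are emitted once.  This matches RDF-graph semantics, and it is
  what keeps the run report, the intermediate Manchester document, and an
  independent reparse of the OWL output in exact agreement.

## ID minting

New-class mode assigns `uri_start + prefix + zfill(n, digits)` with n
counting up from the policy's start ID.  When a target ontology is supplied,
every entity URI matching the exact policy shape (same start portion, same
prefix, same digit width) is scanned and excluded; the allocator fills gaps
at or above the start ID but never allocates below it and never re-issues a
number within a run.  Whether a generator should gap-fill or jump past the
maximum existing ID is a genuine open choice; gap-filling was chosen because
it honors "incrementally assigned from the start ID" while still
guaranteeing collision freedom, and the rule is documented behavior.
Without a target ontology, allocation simply proceeds from the start ID —
with the known pitfall that IDs may duplicate an unseen ontology's; the scan
exists precisely to close that hole.  Capacity is finite (`10^digits −
start` minus scanned IDs at or above start) and is checked up front by
`validate_settings` against the row count.

## The Manchester subset

The expression grammar supports `some`, `only`, `value`, `and`, `or`,
`not`, parentheses, quoted labels (single quotes, doubled-quote escaping),
`<URI>` atoms, and bare CURIE-like tokens resolved against the URI start
portion.  Precedence from loosest to tightest is `or`, `and`, `not`,
restriction; restriction fillers admit only atoms or parenthesized
expressions, mirroring the W3C grammar's `primary` production.
Cardinalities, data ranges, inverse properties, and non-Class frames are
deliberately out of contract: the supported subset covers the OBO-style
patterns this tool exists for, and a smaller grammar is one that can be
round-trip-tested exhaustively.  The renderer emits minimal-parenthesis
canonical text (brackets only where the grammar would otherwise reassociate
or flatten), and `parse(render(e)) = e` structurally — enforced by a
1000-tree randomized property plus agreement with an independently written
split-based reference parser on short expressions.

Label resolution consults the settings' `[Term URIs]` map first, then the
target snapshot's `rdfs:label` index, then fails — listing *all* unknown
labels at once, since fixing them one error at a time is miserable.  A term
used inside a restriction is taken to be an object property; one used in an
annotation pattern, an annotation property; a term playing both roles is a
validation issue rather than a guess.

## The settings dialect

The pattern file is a line-oriented text format: bracketed section headers
(`[Operation]`, `[Term ID]`, `[Key column]`, `[Start portion of term URI]`,
`[Multivalue delimiter]`, `[Term URIs]`, `[Annotations]`,
`[Equivalent classes]`, `[Superclasses]`), one declaration per line, `#`
comments.  It is hand-editable and diffs cleanly, which is the point of a
*reusable* pattern artifact.  Unknown sections warn rather than fail, so
files can carry tool-specific extras.  Serialization is canonical (fixed
section order, normalized quoting) and `parse(serialize(s)) == s`
field-by-field; the canonical form orders equivalent-class patterns before
superclass patterns, so programmatically built settings are normalized to
that order.  Annotation values are plain literals by default with optional
`@lang` or `^^<datatype>` suffixes — patterns in the wild are almost always
plain strings, so plain is the default rather than `xsd:string` tagging.

## Outputs and their agreement

The intermediate Manchester document is written first: one `Class:` frame
per processed row with one `Annotations:` / `SubClassOf:` / `EquivalentTo:`
entry per axiom (one axiom per line, in that order), with all terms in
`<URI>` form so the file is unambiguous without a label map.  The OWL output
is a standalone ontology (IRI = URI start portion + `generated.owl`) meant
for import: new classes are declared `owl:Class`; in edit mode only axioms
are emitted.  Properties used by the axioms are declared with the role
inferred from their use.  Referenced external classes (e.g. a repository
term that lives in the target ontology) are *not* declared — declaring them
here would make reparse counts lie about what the run created — and are
instead listed in a header comment as assumed external.

Because edit mode declares nothing, "class count" agreement between the two
outputs is defined as: Manchester `Class:` frames = distinct subject classes
carrying a declaration or axiom in the RDF graph.  In new-class mode this
equals the declaration count.  Subclass, equivalence, and annotation counts
compare directly.  The RDF/XML writer uses rdflib's plain `xml` serializer:
the pretty-printing serializer drops assertions on RDF-list nodes
(intersection/union operands), which is both lossy and order-sensitive.
Runs are deterministic — byte-identical Manchester text; RDF graphs
isomorphic rather than byte-identical, since blank-node labels are
generated fresh per serialization.

## Synthetic fixtures: what they show and what they do not

All test inputs are generated programmatically.  The cell-line bundle
reconstructs the published worked example from its printed fragments: the
catalogue ID `RCB2320` in row 0 column A, the `"{$columnA} cell"` label
pattern, the tissue/animal comment, and the repository superclass.  Values
only ever shown in screenshots (term URIs, the other rows) are clearly
synthetic placeholders, so the fixture tests the mechanism, not the real
ontology's content.  The Biobank-style bundle exercises edit mode with
definition-editor/definition-source annotation patterns; randomized bundles
draw patterns from the supported grammar over a small vocabulary with
controllable empty-cell rates.  Every bundle carries expectation counts
computed by direct enumeration (regex variable extraction, independent
split and substitution, set-collapse) sharing no code with the engine.

What passing these tests does *not* show: behavior on the original
thousand-row catalogues and live ontologies (external datasets, not
reproducible from the printed record), performance at that scale, spreadsheet
quirks beyond first-sheet/display-text handling, and resolution against
large real label indexes with messy duplicate labels (duplicates are handled
— smallest URI wins, with a warning — but real ontologies exercise this
harder).  Problem sizes in the test suite and acceptance script (3–8-row
tables, 50-bundle sweeps, 100-configuration ID sweeps, 500/1000-case
round-trip sweeps) were chosen as the smallest sizes that exercise every
rule including the Cartesian and collision paths; all of them run in
seconds.

## Degenerate inputs and tie-breaks

Empty tables are valid and yield a header-only ontology.  Ragged tables are
padded to rectangular with empty strings; columns addressed beyond the
width read as empty.  XLSX cells are rendered as display text (integral
floats without `.0`); only the first worksheet is read, with a warning if
more exist.  In edit mode an absolute-URI key is used verbatim, a bare token
is resolved against the URI start portion, an empty key skips the row with
a warning, and a key that is neither (e.g. contains whitespace) is a
row-level error.  Row-level failures abort the run by default —
ontology releases should fail loudly — with `--skip-bad-rows` downgrading
them to warnings.  One operation runs per invocation; multi-step builds are
expected to chain runs in a shell script.
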