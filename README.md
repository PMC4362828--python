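# ontoforge

Batch generation of OWL ontology classes and axioms from spreadsheet
templates and reusable axiom patterns.

## The problem

Biomedical ontologies (vaccine, cell-line, assay, biobank ontologies in the
OBO style) grow by hundreds or thousands of terms that all follow the same
*ontology design pattern*: every cell-line class is `'is in cell line
repository' some <some repository>`, every licensed-vaccine class differs
from its siblings only in pathogen and product name, and so on.  Hand-editing
each class in an ontology editor is slow and error-prone, and it forces
domain experts to learn OWL.  The quick-term-template workflow splits the
work instead: an ontology developer writes the pattern once — axiom
templates in Manchester OWL syntax whose variable parts are spreadsheet
columns — and domain experts fill in a spreadsheet, one row per term.

ontoforge turns the two artifacts into OWL:

* **Axiom settings** — a reusable, diff-friendly text file holding the
  annotation, superclass, and equivalent-class templates (Manchester syntax
  with `{$columnA}`-style variables), the label→URI declarations for every
  quoted term, the URI start portion, and either an auto-ID policy or a key
  column.
* **Input data table** — TSV, CSV, or XLSX; one row per term to generate or
  edit.
* optionally a **target ontology** (RDF/XML or Turtle, file or URL), used to
  avoid minting IDs that already exist and to resolve labels.

Two operation modes cover ontology growth and curation:

* `new_classes` — one new class per non-empty row.  Term URIs are minted as
  `start portion + prefix + zero-padded number` (e.g.
  `http://purl.obolibrary.org/obo/VO_0000001`), counting up from the
  configured start ID and skipping every ID found in the target ontology.
* `edit_existing` — each row names an existing class (key column) and the
  instantiated axioms are attached to it; nothing new is declared.

A pattern referencing an empty cell is dropped for that row rather than
emitting a dangling axiom; multi-valued cells (`a|b`) expand to one axiom
per value.  Each run produces an intermediate **Manchester-syntax document**
(for human debugging) and a standalone **OWL file** (RDF/XML or Turtle)
intended to be merged or `owl:imports`-ed into the target ontology, plus a
run report whose totals can be recomputed from the outputs.

## Worked example

The built-in cell-line bundle reconstructs a repository catalogue pattern:
label annotations `'label' "{$columnA} cell"`, a comment assembled from the
tissue and animal columns, and the superclass
`'is in cell line repository' some 'RIKEN Cell Bank'`.

```sh
$ ontoforge fixtures --name clo --out demo
wrote clo fixture to demo
$ head -2 demo/input.tsv
catalogue ID	originator	register	year	notes	animal	tissue
RCB2320	originator-1	register-1	1991	synthetic note 1	Mus musculus	liver
$ ontoforge run --settings demo/settings.txt --input demo/input.tsv \
      --output demo/cellline.owl --emit-manchester demo/cellline.omn
rows read: 3; processed: 3; classes generated: 3; axioms: {'annotation': 6, 'superclass': 3, 'equivalent': 0}; skipped axioms: 0
```

Three rows became three classes with six annotations (label + comment each)
and three superclass restrictions.  The first frame of the intermediate
document shows the instantiated pattern — the row with catalogue ID
`RCB2320` got the label `"RCB2320 cell"`, a comment built from its tissue
and animal cells, and the repository restriction, under the first minted ID
`CLO_0010000`:

```
Class: <http://purl.obolibrary.org/obo/CLO_0010000>
    Annotations: <http://www.w3.org/2000/01/rdf-schema#label> "RCB2320 cell"
    Annotations: <http://www.w3.org/2000/01/rdf-schema#comment> "Derived from tissue: liver in animal: Mus musculus."
    SubClassOf: <http://purl.obolibrary.org/obo/CLO_9000001> some <http://purl.obolibrary.org/obo/CLO_9000002>
```

`demo/cellline.owl` holds the same content as RDF/XML, ready for import.
`ontoforge validate` checks a settings/table pair without writing anything,
and `ontoforge write-settings` canonicalizes a settings file (applying any
`--id-*`/`--uri-start` overrides) for reuse.

The same library surface is available programmatically:

```python
from ontoforge import parse_settings, run
from ontoforge.fixtures import make_clo_fixture

bundle = make_clo_fixture()
doc, manchester_text, report = run(parse_settings(bundle.settings_text),
                                   bundle.table)
print(report.classes_generated)   # 3
```

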