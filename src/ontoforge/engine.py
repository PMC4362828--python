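"""End-to-end runs: settings + data table + optional target -> outputs + report.

Two operation modes mirror the two things a pattern can do to an ontology:

* ``new_classes`` — mint one new term URI per non-empty data row (collision
  checked against the target-ontology snapshot) and attach the instantiated
  annotation, superclass and equivalent-class axioms;
* ``edit_existing`` — take each row's subject from the key column (an
  absolute URI verbatim, or a bare local ID resolved against the URI start
  portion) and attach new axioms without declaring anything.

Both produce the intermediate Manchester-syntax document and the final OWL
serialization, plus a run report whose totals are recomputable from the
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatable import DataTable, cell
from .errors import RowError, ValidationFailedError
from .id_allocator import IdState, allocate, mint_uri, scan_existing_ids
from .manchester import _SCHEME_RE, render_manchester_document
from .ontology_io import OntologySnapshot, OutputDocument, write_owl
from .settings import OP_EDIT, OP_NEW, AxiomSettings, validate_settings
from .template_engine import GeneratedClass, expand_row

#: appended to the URI start portion to form the output ontology's own IRI
OUTPUT_IRI_SUFFIX = "generated.owl"


@dataclass
class RunReport:
    rows_read: int = 0
    rows_processed: int = 0
    classes_generated: int = 0
    axioms_by_kind: dict[str, int] = field(
        default_factory=lambda: {"annotation": 0, "superclass": 0, "equivalent": 0}
    )
    skipped_axioms: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def make_resolver(settings: AxiomSettings, snapshot: OntologySnapshot | None):
    """Label resolution: settings [Term URIs] first, then the snapshot index."""

    def resolve(label: str):
        uri = settings.term_uris.get(label)
        if uri is None and snapshot is not None:
            uri = snapshot.label_index.get(label)
        return uri

    return resolve


def _validated(settings, table, snapshot):
    issues = validate_settings(settings, table, snapshot=snapshot)
    if issues:
        raise ValidationFailedError(issues)


def _row_is_empty(row: list[str]) -> bool:
    return all(c == "" for c in row)


def _finish(settings, classes, report, output_format):
    for c in classes:
        report.axioms_by_kind["annotation"] += len(c.annotations)
        report.axioms_by_kind["superclass"] += len(c.superclasses)
        report.axioms_by_kind["equivalent"] += len(c.equivalents)
    iri = settings.uri_start + OUTPUT_IRI_SUFFIX
    doc = write_owl(classes, iri, output_format=output_format)
    mdoc = render_manchester_document(classes, ontology_iri=iri)
    return doc, mdoc


def run_new_classes(
    settings: AxiomSettings,
    table: DataTable,
    snapshot: OntologySnapshot | None = None,
    *,
    skip_bad_rows: bool = False,
    output_format: str = "rdfxml",
) -> tuple[OutputDocument, str, RunReport]:
    """Generate one new class per non-empty data row, in row order."""
    if settings.operation != OP_NEW:
        raise ValueError("settings.operation must be new_classes")
    _validated(settings, table, snapshot)

    used = (scan_existing_ids(snapshot, settings.id_policy, settings.uri_start)
            if snapshot is not None else set())
    state = IdState(settings.id_policy, used)
    resolver = make_resolver(settings, snapshot)
    report = RunReport(rows_read=len(table.rows))
    classes: list[GeneratedClass] = []

    for i, row in enumerate(table.rows):
        if _row_is_empty(row):
            continue
        report.rows_processed += 1
        uri = mint_uri(settings.uri_start, allocate(state))
        try:
            gc = expand_row(settings, table, i, uri, resolver,
                            skipped=report.skipped_axioms,
                            warn_list=report.warnings)
        except RowError as exc:
            if skip_bad_rows:
                report.warnings.append(f"row skipped: {exc}")
                continue
            raise
        classes.append(gc)

    report.classes_generated = len(classes)
    doc, mdoc = _finish(settings, classes, report, output_format)
    return doc, mdoc, report


def run_edit_existing(
    settings: AxiomSettings,
    table: DataTable,
    snapshot: OntologySnapshot | None = None,
    *,
    skip_bad_rows: bool = False,
    output_format: str = "rdfxml",
) -> tuple[OutputDocument, str, RunReport]:
    """Attach new axioms to existing classes named by the key column."""
    if settings.operation != OP_EDIT:
        raise ValueError("settings.operation must be edit_existing")
    _validated(settings, table, snapshot)

    resolver = make_resolver(settings, snapshot)
    report = RunReport(rows_read=len(table.rows))
    classes: list[GeneratedClass] = []

    for i, row in enumerate(table.rows):
        if _row_is_empty(row):
            continue
        key = cell(table, i, settings.key_column).strip()
        if key == "":
            report.warnings.append(f"row {i}: empty key cell; row skipped")
            continue
        report.rows_processed += 1
        if _SCHEME_RE.match(key):
            subject = key
        elif any(c.isspace() for c in key):
            exc = RowError(i, settings.key_column,
                           f"key cell {key!r} is neither a URI nor a local ID")
            if skip_bad_rows:
                report.warnings.append(f"row skipped: {exc}")
                continue
            raise exc
        else:
            subject = settings.uri_start + key
        try:
            gc = expand_row(settings, table, i, subject, resolver,
                            skipped=report.skipped_axioms,
                            warn_list=report.warnings)
        except RowError as exc:
            if skip_bad_rows:
                report.warnings.append(f"row skipped: {exc}")
                continue
            raise
        classes.append(gc)

    report.classes_generated = 0  # edit mode declares nothing new
    doc, mdoc = _finish(settings, classes, report, output_format)
    return doc, mdoc, report


def run(settings: AxiomSettings, table: DataTable,
        snapshot: OntologySnapshot | None = None, **kwargs):
    """Dispatch on the settings' operation mode."""
    if settings.operation == OP_NEW:
        return run_new_classes(settings, table, snapshot, **kwargs)
    return run_edit_existing(settings, table, snapshot, **kwargs)
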