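import pytest
from rdflib.compare import isomorphic

from ontoforge.datatable import DataTable
from ontoforge.engine import run, run_edit_existing, run_new_classes
from ontoforge.errors import ValidationFailedError
from ontoforge.fixtures import (
    make_biobank_fixture,
    make_clo_fixture,
    make_random_bundle,
    make_target_ontology,
)
from ontoforge.ontology_io import load_ontology
from ontoforge.settings import IdPolicy, parse_settings

from oracles import manchester_counts, parse_output, rdf_counts

OBO = "http://purl.obolibrary.org/obo/"


def _snapshot(tmp_path, text):
    p = tmp_path / "target.owl"
    p.write_text(text, encoding="utf-8")
    return load_ontology(p)


class TestNewClasses:
    def test_clo_ids_consecutive_from_start(self, clo_run):
        _s, doc, _m, report = clo_run
        assert report.classes_generated == 3
        uris = [c.uri for c in doc.classes]
        assert uris == [OBO + f"CLO_{10000 + i:07d}" for i in range(3)]

    def test_target_collision_shifts_ids(self, tmp_path):
        bundle = make_clo_fixture()
        settings = parse_settings(bundle.settings_text)
        snap = _snapshot(tmp_path,
                         make_target_ontology([10000], IdPolicy("CLO_", 7, 1), OBO))
        doc, _m, report = run_new_classes(settings, bundle.table, snap)
        assert report.classes_generated == 3
        uris = {c.uri for c in doc.classes}
        assert OBO + "CLO_0010000" not in uris
        assert len(uris) == 3 and uris.isdisjoint(snap.entity_uris)

    def test_empty_table_yields_header_only_output(self):
        bundle = make_clo_fixture()
        settings = parse_settings(bundle.settings_text)
        doc, mdoc, report = run_new_classes(settings, DataTable(rows=[]))
        assert report.classes_generated == 0
        assert manchester_counts(mdoc)["classes"] == 0
        assert rdf_counts(doc.serialization)["declarations"] == 0

    def test_fully_empty_rows_skipped(self):
        bundle = make_clo_fixture()
        settings = parse_settings(bundle.settings_text)
        table = DataTable(rows=[list(bundle.table.rows[0]),
                                [""] * bundle.table.width,
                                list(bundle.table.rows[1])])
        _doc, _m, report = run_new_classes(settings, table)
        assert report.rows_read == 3
        assert report.rows_processed == 2 == report.classes_generated

    def test_validation_failure_raises_with_issues(self):
        bundle = make_clo_fixture()
        text = bundle.settings_text.replace(
            "'RIKEN Cell Bank' <http://purl.obolibrary.org/obo/CLO_9000002>\n", "")
        with pytest.raises(ValidationFailedError) as exc:
            run(parse_settings(text), bundle.table)
        assert any(i.kind == "unknown_label" for i in exc.value.issues)


class TestEditExisting:
    def test_biobank_counts(self):
        bundle = make_biobank_fixture(5)
        settings = parse_settings(bundle.settings_text)
        doc, _m, report = run_edit_existing(settings, bundle.table)
        assert report.classes_generated == 0
        assert report.axioms_by_kind["annotation"] == 10
        assert rdf_counts(doc.serialization)["declarations"] == 0

    def test_empty_source_cell_skips_one_annotation(self):
        bundle = make_biobank_fixture(1, empty_source_rows=[0])
        settings = parse_settings(bundle.settings_text)
        doc, _m, report = run_edit_existing(settings, bundle.table)
        assert report.axioms_by_kind["annotation"] == 1
        assert len(report.skipped_axioms) == 1

    def test_subject_taken_verbatim_from_key_uri(self):
        bundle = make_biobank_fixture(1)
        settings = parse_settings(bundle.settings_text)
        key = bundle.table.rows[0][0]
        doc, _m, _r = run_edit_existing(settings, bundle.table)
        assert doc.classes[0].uri == key

    def test_bare_local_id_resolved_against_uri_start(self):
        bundle = make_biobank_fixture(1)
        bundle.table.rows[0][0] = "BIOBANK_9000042"
        settings = parse_settings(bundle.settings_text)
        doc, _m, _r = run_edit_existing(settings, bundle.table)
        assert doc.classes[0].uri == OBO + "BIOBANK_9000042"

    def test_empty_key_cell_skipped_with_warning(self):
        bundle = make_biobank_fixture(2)
        bundle.table.rows[0][0] = ""
        settings = parse_settings(bundle.settings_text)
        _doc, _m, report = run_edit_existing(settings, bundle.table)
        assert report.rows_processed == 1
        assert any("empty key" in w for w in report.warnings)


class TestReportConsistency:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_axiom_totals_match_reparse(self, seed):
        bundle = make_random_bundle(seed, rows=6, patterns=4, empty_rate=0.25)
        settings = parse_settings(bundle.settings_text)
        doc, mdoc, report = run(settings, bundle.table)
        counts = rdf_counts(doc.serialization)
        assert counts["annotations"] == report.axioms_by_kind["annotation"]
        assert counts["superclasses"] == report.axioms_by_kind["superclass"]
        assert counts["equivalents"] == report.axioms_by_kind["equivalent"]
        assert counts["declarations"] == report.classes_generated

    def test_one_existential_keyword_per_row_in_intermediate(self, clo_run):
        _s, _doc, mdoc, report = clo_run
        assert mdoc.count(" some ") == report.rows_processed == 3

    def test_permuting_rows_permutes_outputs(self):
        """No cross-row leakage: reversed rows yield the same axiom sets,
        only the minted-ID order follows row order."""
        bundle = make_clo_fixture()
        settings = parse_settings(bundle.settings_text)
        doc_fwd, _m, _r = run_new_classes(settings, bundle.table)
        reversed_table = DataTable(rows=[list(r) for r in
                                         reversed(bundle.table.rows)])
        doc_rev, _m, _r = run_new_classes(parse_settings(bundle.settings_text),
                                          reversed_table)

        def keyed(doc):
            return {tuple(sorted(v for (_p, v, _t) in c.annotations))
                    for c in doc.classes}

        assert keyed(doc_fwd) == keyed(doc_rev)
        assert [c.uri for c in doc_fwd.classes] == \
            [c.uri for c in doc_rev.classes]  # IDs follow row order

    def test_intermediate_and_final_agree(self, clo_run):
        _s, doc, mdoc, _r = clo_run
        m = manchester_counts(mdoc)
        r = rdf_counts(doc.serialization)
        assert m["classes"] == r["classes"]
        assert m["superclasses"] == r["superclasses"]
        assert m["annotations"] == r["annotations"]


class TestDeterminism:
    def test_repeat_runs_identical(self):
        bundle = make_random_bundle(11, rows=5, patterns=3, empty_rate=0.2)
        settings = parse_settings(bundle.settings_text)
        doc1, m1, _ = run(settings, bundle.table)
        doc2, m2, _ = run(parse_settings(bundle.settings_text), bundle.table)
        assert m1 == m2  # byte-identical intermediate document
        assert isomorphic(parse_output(doc1.serialization),
                          parse_output(doc2.serialization))
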