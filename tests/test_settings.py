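import warnings

import pytest
from hypothesis import given, strategies as st

from ontoforge.datatable import DataTable
from ontoforge.errors import SettingsError
from ontoforge.fixtures import make_clo_fixture, make_random_settings
from ontoforge.settings import (
    AxiomSettings,
    IdPolicy,
    TermUriMap,
    parse_settings,
    serialize_settings,
    validate_settings,
)

MINIMAL_NEW = """\
[Operation]
new_classes

[Term ID]
prefix=VO_ digits=7 start=10000

[Start portion of term URI]
http://purl.obolibrary.org/obo/

[Annotations]
'label' "{$columnA} vaccine"

[Term URIs]
'label' <http://www.w3.org/2000/01/rdf-schema#label>
"""


class TestParse:
    def test_minimal_new_classes_file(self):
        s = parse_settings(MINIMAL_NEW)
        assert s.operation == "new_classes"
        assert s.id_policy == IdPolicy("VO_", 7, 10000)
        assert len(s.annotation_patterns) == 1
        assert s.annotation_patterns[0].value_template == "{$columnA} vaccine"

    def test_clo_fixture_settings(self):
        s = parse_settings(make_clo_fixture().settings_text)
        sup = [p for p in s.expression_patterns if p.kind == "superclass"]
        assert len(sup) == 1
        assert "'is in cell line repository' some 'RIKEN Cell Bank'" == sup[0].template
        assert len(s.annotation_patterns) >= 2

    def test_comments_and_blank_lines_ignored(self):
        s = parse_settings("# top comment\n\n" + MINIMAL_NEW + "\n# trailing\n")
        assert s.id_policy.prefix == "VO_"

    def test_unknown_section_warns_not_errors(self):
        with pytest.warns(UserWarning, match="unknown section"):
            s = parse_settings(MINIMAL_NEW + "\n[Mystery]\nstuff\n")
        assert s.operation == "new_classes"

    def test_missing_mandatory_section_named_in_error(self):
        text = MINIMAL_NEW.replace("[Term ID]\nprefix=VO_ digits=7 start=10000\n", "")
        with pytest.raises(SettingsError, match=r"\[Term ID\]"):
            parse_settings(text)
        with pytest.raises(SettingsError, match=r"\[Key column\]"):
            parse_settings(text.replace("new_classes", "edit_existing"))

    def test_malformed_id_policy_line_reports_line_number(self):
        text = MINIMAL_NEW.replace("prefix=VO_ digits=7 start=10000",
                                   "prefix=VO_ digits=seven")
        with pytest.raises(SettingsError, match="line 5"):
            parse_settings(text)

    def test_annotation_language_suffix(self):
        text = MINIMAL_NEW.replace(
            '\'label\' "{$columnA} vaccine"',
            '\'label\' "{$columnA} vaccine"@en',
        )
        s = parse_settings(text)
        assert s.annotation_patterns[0].tag == "@en"

    def test_duplicate_term_uri_label_rejected(self):
        text = MINIMAL_NEW + "'label' <http://example.org/other>\n"
        with pytest.raises(SettingsError, match="duplicate"):
            parse_settings(text)


class TestSerialize:
    def test_minimal_settings_round_trip(self):
        s = parse_settings(MINIMAL_NEW)
        assert parse_settings(serialize_settings(s)) == s

    def test_canonical_form_is_a_fixed_point(self):
        canonical = serialize_settings(parse_settings(MINIMAL_NEW))
        assert serialize_settings(parse_settings(canonical)) == canonical

    def test_clo_serialization_contains_variable_token(self):
        s = parse_settings(make_clo_fixture().settings_text)
        assert "{$columnA}" in serialize_settings(s)

    def test_emitted_files_parse_without_warnings(self):
        s = parse_settings(make_clo_fixture().settings_text)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            parse_settings(serialize_settings(s))

    def test_invalid_settings_rejected(self):
        s = AxiomSettings(operation="new_classes", term_uris=TermUriMap({}),
                          uri_start="http://x.org/", id_policy=None)
        with pytest.raises(ValueError):
            serialize_settings(s)


@given(st.integers(min_value=0, max_value=100_000))
def test_settings_round_trip_randomized(seed):
    """parse(serialize(s)) == s field-by-field for randomized settings."""
    s = make_random_settings(seed)
    assert parse_settings(serialize_settings(s)) == s


class TestValidate:
    def _table(self, cols=3, rows=2):
        return DataTable(rows=[[f"r{i}c{j}" for j in range(cols)]
                               for i in range(rows)])

    def test_out_of_range_column(self):
        s = parse_settings(MINIMAL_NEW.replace("{$columnA}", "{$columnZ}"))
        issues = validate_settings(s, self._table(cols=3))
        assert [i.kind for i in issues] == ["out_of_range_column"]

    def test_known_label_produces_no_issue(self):
        bundle = make_clo_fixture()
        s = parse_settings(bundle.settings_text)
        assert validate_settings(s, bundle.table) == []

    def test_unknown_label_flagged(self):
        bundle = make_clo_fixture()
        text = bundle.settings_text.replace(
            "'RIKEN Cell Bank' <http://purl.obolibrary.org/obo/CLO_9000002>\n", "")
        issues = validate_settings(parse_settings(text), bundle.table)
        assert any(i.kind == "unknown_label" and "RIKEN Cell Bank" in i.message
                   for i in issues)

    def test_id_capacity_counted_by_enumeration(self):
        # 10^2 - 95 = 5 IDs available for 10 rows
        s = parse_settings(MINIMAL_NEW.replace("prefix=VO_ digits=7 start=10000",
                                               "prefix=VO_ digits=2 start=95"))
        issues = validate_settings(s, self._table(cols=3, rows=10))
        capacity = [i for i in issues if i.kind == "id_capacity"]
        assert len(capacity) == 1
        assert "5" in capacity[0].message

    def test_edit_without_key_column(self):
        s = parse_settings(make_clo_fixture().settings_text)
        s.operation = "edit_existing"
        s.key_column = None
        issues = validate_settings(s, self._table())
        assert any(i.kind == "missing_key_column" for i in issues)

    def test_property_role_conflict(self):
        bundle = make_clo_fixture()
        # reuse the repository object property as an annotation property
        text = bundle.settings_text.replace(
            "[Annotations]",
            "[Annotations]\n'is in cell line repository' \"{$columnA}\"",
        )
        issues = validate_settings(parse_settings(text), bundle.table)
        assert any(i.kind == "property_role_conflict" for i in issues)

    def test_template_syntax_issue(self):
        bundle = make_clo_fixture()
        text = bundle.settings_text.replace(
            "'is in cell line repository' some 'RIKEN Cell Bank'",
            "'is in cell line repository' some and",
        )
        issues = validate_settings(parse_settings(text), bundle.table)
        assert any(i.kind == "template_syntax" for i in issues)
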