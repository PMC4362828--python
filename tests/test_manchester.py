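import random

import pytest
from hypothesis import given, strategies as st

from ontoforge.errors import LabelResolutionError, ManchesterSyntaxError
from ontoforge.fixtures import random_class_expression
from ontoforge.manchester import (
    And,
    HasValue,
    Named,
    Not,
    Only,
    Or,
    Some,
    TermRef,
    parse_class_expression,
    render_class_expression,
    render_manchester_document,
)
from ontoforge.template_engine import GeneratedClass

from oracles import manchester_counts, ref_parse, structural_tokens

URIS = {
    "is in cell line repository": "http://purl.obolibrary.org/obo/CLO_9000001",
    "RIKEN Cell Bank": "http://purl.obolibrary.org/obo/CLO_9000002",
    "derived from": "http://purl.obolibrary.org/obo/RO_9000123",
    "liver": "http://purl.obolibrary.org/obo/UBERON_9000456",
    "part of": "http://purl.obolibrary.org/obo/BFO_9000050",
    "Mus musculus": "http://purl.obolibrary.org/obo/NCBITaxon_10090",
}


def resolver(label):
    return URIS.get(label)


def ref(label):
    return TermRef.from_label(label, URIS[label])


class TestParse:
    def test_repository_superclass_pattern(self):
        e = parse_class_expression(
            "'is in cell line repository' some 'RIKEN Cell Bank'", resolver
        )
        assert e == Some(ref("is in cell line repository"),
                         Named(ref("RIKEN Cell Bank")))

    def test_nested_tissue_pattern(self):
        e = parse_class_expression(
            "'derived from' some ('liver' and 'part of' some 'Mus musculus')",
            resolver,
        )
        assert e == Some(
            ref("derived from"),
            And((Named(ref("liver")),
                 Some(ref("part of"), Named(ref("Mus musculus"))))),
        )

    def test_bare_atom(self):
        assert parse_class_expression("'RIKEN Cell Bank'", resolver) == Named(
            ref("RIKEN Cell Bank")
        )

    def test_precedence_or_lowest(self):
        e = parse_class_expression(
            "'liver' and 'Mus musculus' or not 'RIKEN Cell Bank'", resolver
        )
        assert isinstance(e, Or)
        assert isinstance(e.operands[0], And)
        assert isinstance(e.operands[1], Not)

    def test_angle_bracket_and_bare_curie_atoms(self):
        e = parse_class_expression(
            "<http://example.org/x> and EX_0000001", resolver,
            uri_start="http://purl.obolibrary.org/obo/",
        )
        a, b = e.operands
        assert a.term.uri == "http://example.org/x"
        assert b.term.uri == "http://purl.obolibrary.org/obo/EX_0000001"

    def test_value_restriction(self):
        e = parse_class_expression("'part of' value 'liver'", resolver)
        assert e == HasValue(ref("part of"), ref("liver"))

    def test_unresolvable_labels_all_reported(self):
        with pytest.raises(LabelResolutionError) as exc:
            parse_class_expression("'nope one' some ('liver' and 'nope two')",
                                   resolver)
        assert exc.value.labels == ["nope one", "nope two"]

    @pytest.mark.parametrize("bad", [
        "", "'liver' and", "( 'liver'", "'liver' 'Mus musculus'",
        "some 'liver'", "'unterminated",
    ])
    def test_syntax_errors_are_positioned(self, bad):
        with pytest.raises(ManchesterSyntaxError) as exc:
            parse_class_expression(bad, resolver)
        assert exc.value.pos >= 0


class TestRender:
    def test_named(self):
        assert render_class_expression(Named(ref("RIKEN Cell Bank"))) == \
            "'RIKEN Cell Bank'"

    def test_existential(self):
        e = Some(ref("is in cell line repository"), Named(ref("RIKEN Cell Bank")))
        assert render_class_expression(e) == \
            "'is in cell line repository' some 'RIKEN Cell Bank'"

    def test_label_with_apostrophe_is_escaped(self):
        t = TermRef.from_label("O'Hara cell", "http://example.org/o")
        text = render_class_expression(Named(t))
        assert text == "'O''Hara cell'"
        back = parse_class_expression(text, {"O'Hara cell": "http://example.org/o"}.get)
        assert back == Named(t)

    def test_uri_style_rendering(self):
        e = Some(ref("part of"), Named(ref("liver")))
        assert render_class_expression(e, term_style="uri") == (
            "<http://purl.obolibrary.org/obo/BFO_9000050> some "
            "<http://purl.obolibrary.org/obo/UBERON_9000456>"
        )


@given(st.integers(min_value=0, max_value=10_000))
def test_render_parse_round_trip(seed):
    """parse(render(e)) is structurally identical for random trees."""
    rng = random.Random(seed)
    expr, res = random_class_expression(rng, max_depth=5)
    text = render_class_expression(expr)
    assert parse_class_expression(text, res) == expr


@given(st.integers(min_value=0, max_value=10_000))
def test_parser_matches_reference_on_small_expressions(seed):
    """On short expressions the streaming parser agrees with the
    split-based reference parser."""
    rng = random.Random(seed)
    expr, res = random_class_expression(rng, max_depth=3)
    text = render_class_expression(expr)
    if len(structural_tokens(text)) <= 4:
        assert ref_parse(text, res) == parse_class_expression(text, res)


class TestDocument:
    def test_empty_class_list(self):
        doc = render_manchester_document([], ontology_iri="http://example.org/o")
        counts = manchester_counts(doc)
        assert counts == {"classes": 0, "annotations": 0, "superclasses": 0,
                          "equivalents": 0}
        assert "Ontology: <http://example.org/o>" in doc

    def test_single_frame_counts(self):
        gc = GeneratedClass(
            uri="http://example.org/X_1",
            annotations=[("http://www.w3.org/2000/01/rdf-schema#label",
                          'say "hi"', None)],
            superclasses=[Some(ref("part of"), Named(ref("liver")))],
        )
        doc = render_manchester_document([gc], ontology_iri="http://example.org/o")
        counts = manchester_counts(doc)
        assert counts["classes"] == 1
        assert counts["superclasses"] == 1
        assert counts["annotations"] == 1
        assert '\\"hi\\"' in doc  # literal quoting is escaped

    def test_language_tag_and_datatype_suffixes(self):
        gc = GeneratedClass(
            uri="http://example.org/X_1",
            annotations=[("http://example.org/p", "bonjour", "@fr"),
                         ("http://example.org/q", "5",
                          "http://www.w3.org/2001/XMLSchema#integer")],
        )
        doc = render_manchester_document([gc])
        assert '"bonjour"@fr' in doc
        assert '"5"^^<http://www.w3.org/2001/XMLSchema#integer>' in doc
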