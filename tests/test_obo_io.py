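"""Format readers/writers: OBO subset, functional syntax, SSSOM, OBO Graph."""

import json

import pytest

from eqtraits.io import (parse_functional_syntax, parse_obo, parse_sssom,
                         write_functional_syntax, write_obo,
                         write_obograph_json, write_sssom)
from eqtraits.io.obo import OboParseError
from eqtraits.io.sssom import (JUSTIFICATION_LEXICAL, JUSTIFICATION_LOGICAL,
                               SSSOMRow)
from eqtraits.model import (Curie, EquivalentTo, Named, OntologyError, Some,
                            SubClassOf, UnsupportedConstructError,
                            parse_curie)
from eqtraits.relgraph import RelationEdge


def test_parse_obo_relationship_becomes_existential():
    text = """
[Term]
id: UBERON:0001424
name: ulna
relationship: BFO:0000050 UBERON:0001440

[Term]
id: UBERON:0001440
name: forelimb skeleton

[Typedef]
id: BFO:0000050
name: part of
"""
    ont = parse_obo(text)
    ulna = parse_curie("UBERON:0001424")
    expected = SubClassOf(Named(ulna),
                          Some(parse_curie("BFO:0000050"),
                               Named(parse_curie("UBERON:0001440"))))
    assert expected in ont.axioms
    assert ont.terms[ulna].label == "ulna"


def test_parse_obo_intersection_of_becomes_one_equivalence():
    text = """
[Term]
id: OBA:0002360
name: trochanter size
intersection_of: PATO:0000117
intersection_of: RO:0000052 UBERON:0000980
"""
    ont = parse_obo(text)
    equiv = ont.equiv_for(parse_curie("OBA:0002360"))
    assert equiv is not None
    assert len(equiv.expr.operands) == 2


def test_parse_obo_obsolete_stanza_has_no_axioms():
    text = """
[Term]
id: OBA:0000001
name: obsolete head size
is_obsolete: true
replaced_by: OBA:0000002
"""
    ont = parse_obo(text)
    rec = ont.terms[parse_curie("OBA:0000001")]
    assert rec.deprecated
    assert rec.label.startswith("obsolete ")
    assert rec.replaced_by == parse_curie("OBA:0000002")
    assert ont.axioms == []


def test_parse_obo_obsolete_with_logical_tags_is_hard_error():
    text = """
[Term]
id: OBA:0000001
name: obsolete head size
is_obsolete: true
is_a: OBA:0000009
"""
    with pytest.raises(OboParseError):
        parse_obo(text)


def test_parse_obo_empty_document_and_unknown_tag():
    assert parse_obo("").terms == {}
    with pytest.warns(UserWarning):
        ont = parse_obo("[Term]\nid: OBA:0000003\nxref: FOO:1\n")
    assert parse_curie("OBA:0000003") in ont.terms


def test_obo_write_parse_round_trip(bundle):
    for ont in (bundle.mini_anatomy, bundle.mini_chemical,
                bundle.mini_characteristics):
        text = write_obo(ont)
        back = parse_obo(text)
        assert back.canonical_axiom_set() == ont.canonical_axiom_set()
        assert set(back.terms) == set(ont.terms)
        assert back.subsets == ont.subsets


def test_functional_syntax_round_trip_on_fixtures(bundle, traits):
    for ont in (bundle.mini_anatomy, bundle.mini_chemical,
                bundle.mini_characteristics, bundle.mini_phenotype,
                bundle.roles, traits):
        text = write_functional_syntax(ont)
        back = parse_functional_syntax(text)
        assert back.canonical_axiom_set() == ont.canonical_axiom_set()
        assert set(back.terms) == set(ont.terms)
        for cid, rec in ont.terms.items():
            assert back.terms[cid].label == rec.label
            assert back.terms[cid].deprecated == rec.deprecated
        # writers are deterministic byte-for-byte
        assert write_functional_syntax(back) == text


def test_functional_syntax_empty_ontology_is_header_only():
    from eqtraits.model import Ontology
    text = write_functional_syntax(Ontology())
    back = parse_functional_syntax(text)
    assert back.terms == {} and back.axioms == []


def test_functional_syntax_parses_gci_and_chain():
    text = """\
Prefix(TST:=<http://purl.obolibrary.org/obo/TST_>)
Ontology(<http://example.org/t>
Declaration(Class(TST:A))
Declaration(Class(TST:B))
Declaration(ObjectProperty(TST:r))
Declaration(ObjectProperty(TST:s))
Declaration(ObjectProperty(TST:t))
SubClassOf(ObjectIntersectionOf(TST:A TST:B) TST:A)
SubObjectPropertyOf(ObjectPropertyChain(TST:r TST:s) TST:t)
)
"""
    ont = parse_functional_syntax(text)
    from eqtraits.model import And, RoleChain
    gcis = [ax for ax in ont.axioms
            if isinstance(ax, SubClassOf) and isinstance(ax.sub, And)]
    assert len(gcis) == 1
    chains = [ax for ax in ont.axioms if isinstance(ax, RoleChain)]
    assert chains == [RoleChain(parse_curie("TST:r"), parse_curie("TST:s"),
                                parse_curie("TST:t"))]


def test_functional_syntax_rejects_beyond_el():
    text = """\
Prefix(TST:=<http://purl.obolibrary.org/obo/TST_>)
Ontology(<http://example.org/t>
SubClassOf(TST:A ObjectUnionOf(TST:B TST:C))
)
"""
    with pytest.raises(UnsupportedConstructError):
        parse_functional_syntax(text)


def _rows(n):
    return [SSSOMRow(subject_id=Curie("MP", f"{i:07d}"),
                     subject_label=f"pheno {i}",
                     predicate_id="skos:broadMatch",
                     object_id=Curie("OBA", f"{i:07d}"),
                     object_label=f"trait {i}",
                     mapping_justification=JUSTIFICATION_LOGICAL)
            for i in range(n)]


def test_write_sssom_counts_and_confidence_absence():
    header_only = write_sssom([], metadata={"mapping_set_id": "x"})
    lines = header_only.strip().split("\n")
    assert lines[0].startswith("#") and lines[1].startswith("subject_id")
    assert len(lines) == 2

    five = write_sssom(_rows(5))
    data = [l for l in five.strip().split("\n") if not l.startswith("#")][1:]
    assert len(data) == 5 and all("\t" in l for l in data)

    row = SSSOMRow(subject_id=Curie("VT", "0000001"), subject_label="x",
                   predicate_id="skos:exactMatch",
                   object_id=Curie("OBA", "0000001"), object_label="y",
                   mapping_justification=JUSTIFICATION_LEXICAL)
    line = write_sssom([row]).rstrip("\n").split("\n")[-1]
    assert line.endswith("\t")  # absent confidence is empty, not 0
    assert parse_sssom(write_sssom([row]))[0].confidence is None


def test_sssom_rejects_unknown_justification():
    with pytest.raises(OntologyError):
        SSSOMRow(subject_id=Curie("VT", "1"), subject_label="",
                 predicate_id="skos:exactMatch",
                 object_id=Curie("OBA", "1"), object_label="",
                 mapping_justification="GuessWork")


def test_obograph_json(bundle):
    empty = json.loads(write_obograph_json(
        __import__("eqtraits.model", fromlist=["Ontology"]).Ontology()))
    assert empty == {"nodes": [], "edges": []}

    doc = json.loads(write_obograph_json(bundle.mini_anatomy))
    assert len(doc["nodes"]) == len(bundle.mini_anatomy.terms)

    edge = RelationEdge(Curie("OBA", "1000003"), Curie("BFO", "0000050"),
                        Curie("OBA", "1000004"))
    doc = json.loads(write_obograph_json(bundle.mini_anatomy, {edge}))
    assert doc["edges"] == [{"sub": "OBA:1000003", "pred": "BFO:0000050",
                             "obj": "OBA:1000004"}]
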