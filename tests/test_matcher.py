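"""Lexical matching, normalisation, decomposition and review round-trip."""

import pytest
from hypothesis import given, settings, strategies as st

from eqtraits import fixtures as fx
from eqtraits.matching import (DEFAULT_STOPLIST, MatchCandidate,
                               apply_review, match_and_decompose,
                               match_terms, normalize_label,
                               propose_decomposition, write_candidates_tsv)
from eqtraits.model import Curie, IdMinter, OntologyError


@pytest.fixture(scope="module")
def refs_ordered(bundle):
    # chemicals first, then anatomy, then characteristics (match order)
    return [bundle.mini_chemical, bundle.mini_anatomy,
            bundle.mini_characteristics]


@pytest.fixture(scope="module")
def external():
    return fx.external_vocabulary()


@pytest.mark.parametrize("text, expected", [
    ("Lysine measurement", ["lysine"]),
    ("trait", []),
    ("Blood glucose (fasting) Trait", ["blood", "glucose", "fasting"]),
    ("head circumference trait", ["head", "circumference"]),
])
def test_normalize_label(text, expected):
    assert normalize_label(text) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(max_size=40))
def test_normalize_label_is_idempotent(text):
    once = normalize_label(text)
    assert normalize_label(" ".join(once)) == once


def test_exact_match_fixture_set(external, traits):
    candidates = match_terms(external, traits)
    by_id = {str(c.external_id): c for c in candidates}
    exact = [c for c in candidates if c.kind.startswith("EXACT")]
    assert len(exact) == 8
    assert by_id["VT:0000001"].kind == "EXACT_LABEL"
    assert by_id["VT:0000001"].matched_trait == fx.HEAD_SIZE
    assert by_id["VT:0000007"].matched_trait == fx.HEAD_CIRCUMFERENCE
    assert by_id["VT:0000008"].kind == "EXACT_SYNONYM"
    assert by_id["VT:0000008"].matched_trait == fx.BLOOD_GLUCOSE_AMOUNT
    # no false exact matches
    for c in exact:
        assert c.matched_trait is not None
        trait_label = traits.terms[c.matched_trait].label
        forms = {tuple(normalize_label(trait_label))} | {
            tuple(normalize_label(s))
            for s in traits.terms[c.matched_trait].exact_synonyms()}
        ext_forms = {tuple(normalize_label(c.external_label))} | {
            tuple(normalize_label(s))
            for s in external.terms[c.external_id].exact_synonyms()}
        assert forms & ext_forms
    assert by_id["VT:0000009"].kind == "NONE"
    assert by_id["VT:0000010"].kind == "NONE"


def test_ambiguous_trait_targets_yield_none_with_note(traits):
    from eqtraits.model import Ontology
    external = Ontology()
    external.add_term(Curie("VT", "0000099"), "head size")
    ambiguous = traits.copy()
    dup = Curie("OBA", "7777777")
    ambiguous.add_term(dup, "Head Size trait")  # normalises identically
    from eqtraits.model import EquivalentTo, Named
    ambiguous.add_axiom(EquivalentTo(dup, Named(fx.HEAD_SIZE)))
    candidates = match_terms(external, ambiguous)
    assert candidates[0].kind == "NONE"
    assert "ambiguous" in candidates[0].note


def test_decomposition_lysine_measurement(bundle, refs_ordered):
    cand = propose_decomposition("lysine measurement", refs_ordered,
                                 bundle.patterns)
    assert cand.kind == "DECOMPOSITION"
    assert cand.pattern_id == "entity-attribute"
    assert cand.proposed_bindings == {"entity": fx.LYSINE}


def test_decomposition_blood_lysine_amount(bundle, refs_ordered):
    cand = propose_decomposition("blood lysine amount", refs_ordered,
                                 bundle.patterns)
    assert cand.kind == "DECOMPOSITION"
    assert cand.pattern_id == "chemical-in-entity-attribute"
    assert cand.proposed_bindings == {"location": fx.BLOOD,
                                      "chemical": fx.LYSINE,
                                      "attribute": fx.AMOUNT}


def test_decomposition_no_reference_hit(bundle, refs_ordered):
    cand = propose_decomposition("xyzzy measurement", refs_ordered,
                                 bundle.patterns)
    assert cand.kind == "NONE"
    assert propose_decomposition("trait", refs_ordered,
                                 bundle.patterns).kind == "NONE"


def test_match_before_sync_no_candidate_is_both(external, traits, bundle,
                                                refs_ordered):
    candidates = match_and_decompose(external, traits, refs_ordered,
                                     bundle.patterns)
    kinds = {str(c.external_id): c.kind for c in candidates}
    assert kinds["VT:0000009"] == "DECOMPOSITION"
    assert sum(k.startswith("EXACT") for k in kinds.values()) == 8
    assert sum(k == "DECOMPOSITION" for k in kinds.values()) == 1
    # exact matches never carry decomposition bindings
    for c in candidates:
        if c.kind.startswith("EXACT"):
            assert not c.proposed_bindings


def test_apply_review_flows(external, traits, bundle, refs_ordered):
    candidates = match_and_decompose(external, traits, refs_ordered,
                                     bundle.patterns)
    # all rejected -> empty outputs
    review = "candidate_id\tdecision\n" + "\n".join(
        f"{c.external_id}\tREJECTED" for c in candidates)
    rows, fillers = apply_review(candidates, review)
    assert rows == [] and fillers == []

    # one accepted exact + one accepted decomposition
    review = ("candidate_id\tdecision\n"
              "VT:0000001\tACCEPTED\n"
              "VT:0000009\tACCEPTED\n")
    minter = IdMinter(start=9200001)
    rows, fillers = apply_review(candidates, review, minter=minter)
    assert len(rows) == 1
    assert rows[0].object_id == fx.HEAD_SIZE
    assert rows[0].mapping_justification == "semapv:LexicalMatching"
    assert len(fillers) == 1
    assert fillers[0].defined_class == Curie("OBA", "9200001")
    assert fillers[0].bindings == {"entity": fx.LYSINE}


def test_apply_review_unknown_candidate_is_error(external, traits):
    candidates = match_terms(external, traits)
    with pytest.raises(OntologyError, match="unknown candidate"):
        apply_review(candidates, "candidate_id\tdecision\nVT:404\tACCEPTED\n")


def test_accepted_decomposition_compiles_to_matching_label(bundle, refs):
    """An accepted decomposition, once compiled, produces a term whose
    normalised label equals the external term's normalised label."""
    from eqtraits.patterns import FillerRow, compile_row
    cand = propose_decomposition(
        "blood lysine amount",
        [bundle.mini_chemical, bundle.mini_anatomy,
         bundle.mini_characteristics],
        bundle.patterns)
    pattern = bundle.pattern_by_id(cand.pattern_id)
    row = FillerRow(Curie("OBA", "9300001"), dict(cand.proposed_bindings))
    record, _ = compile_row(pattern, row, refs)
    assert normalize_label(record.label) == \
        normalize_label("blood lysine amount")


def test_candidates_tsv_round_trip_shape(external, traits):
    text = write_candidates_tsv(match_terms(external, traits))
    lines = text.strip().split("\n")
    assert lines[0].startswith("external_id\t")
    assert len(lines) == len(external.terms) + 1
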