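"""Phenotype -> trait link extraction and manifestation queries."""

import pytest

from eqtraits import fixtures as fx
from eqtraits.linking import (LinkSummary, link_phenotypes, manifestations)
from eqtraits.model import Named, Ontology
from eqtraits.reasoner import classify, entails


@pytest.fixture(scope="module")
def links(release, bundle):
    return link_phenotypes(release, bundle.mini_phenotype)


def _mapping(rows):
    return {(str(r.subject_id), str(r.object_id)) for r in rows}


def test_each_abnormality_maps_to_its_intended_attribute(links):
    rows, _ = links
    mapping = _mapping(rows)
    expected = {
        (str(fx.HYPOLYSINEMIA), str(fx.BLOOD_LYSINE_AMOUNT)),
        (str(fx.HYPERGLYCEMIA), str(fx.BLOOD_GLUCOSE_AMOUNT)),
        (str(fx.DECREASED_HEAD_CIRCUMFERENCE), str(fx.HEAD_CIRCUMFERENCE)),
        (str(fx.MICROCEPHALY), str(fx.HEAD_CIRCUMFERENCE)),
        (str(fx.PROGRESSIVE_MICROCEPHALY), str(fx.HEAD_CIRCUMFERENCE)),
        (str(fx.VENTRICULOMEGALY), str(fx.BRAIN_VENTRICLE_SIZE)),
    }
    assert expected <= mapping


def test_undecomposable_classes_are_unmapped(links):
    _, summary = links
    assert fx.ABNORMAL_GAIT in summary.unmapped
    assert fx.PREWEANING_LETHALITY in summary.unmapped


def test_summary_counts_are_consistent(links, bundle):
    rows, summary = links
    assert summary.links == len(rows)
    assert summary.classes_under_root <= len(
        bundle.mini_phenotype.live_terms())
    assert summary.classes_under_root == 6


def test_every_row_reverifies_via_entails(links, release, bundle):
    rows, _ = links
    merged = release.merge(bundle.mini_phenotype)
    for row in rows:
        assert entails(merged, Named(row.subject_id),
                       Named(row.object_id)), \
            f"{row.subject_id} -> {row.object_id}"


def test_nonredundant_rows_are_deepest(links, release, bundle):
    """Microcephaly sits under both head circumference and head size;
    only the deeper attribute is emitted by default."""
    rows, _ = links
    mapping = _mapping(rows)
    assert (str(fx.MICROCEPHALY), str(fx.HEAD_SIZE)) not in mapping
    closure_rows, _ = link_phenotypes(release, bundle.mini_phenotype,
                                      emit_closure=True)
    closure_mapping = _mapping(closure_rows)
    assert (str(fx.MICROCEPHALY), str(fx.HEAD_SIZE)) in closure_mapping
    assert mapping <= closure_mapping


def test_link_extraction_is_idempotent(links, release, bundle):
    rows_again, summary_again = link_phenotypes(release,
                                                bundle.mini_phenotype)
    assert rows_again == links[0]
    assert summary_again.links == links[1].links


def test_disjoint_vocabularies_warn_and_return_empty():
    from eqtraits.model import Curie, EquivalentTo, And, Some, SubClassOf
    traits = Ontology()
    traits.add_term(Curie("OBA", "0000001"), "biological attribute")
    pheno = Ontology()
    pheno.add_term(Curie("MP", "0000002"), "some phenotype")
    pheno.add_role(Curie("RO", "0000052"))
    pheno.add_term(Curie("MP", "0000003"), "state")
    pheno.add_axiom(EquivalentTo(
        Curie("MP", "0000002"),
        And((Named(Curie("MP", "0000003")),
             Some(Curie("RO", "0000052"), Named(Curie("TST", "X")))))))
    with pytest.warns(UserWarning, match="share no reference"):
        rows, summary = link_phenotypes(traits, pheno)
    assert rows == [] and summary.links == 0


def test_manifestations_of_head_circumference(merged_with_phenotypes):
    states = manifestations(merged_with_phenotypes, fx.HEAD_CIRCUMFERENCE)
    assert states == {fx.DECREASED_HEAD_CIRCUMFERENCE, fx.MICROCEPHALY,
                      fx.PROGRESSIVE_MICROCEPHALY}


def test_manifestations_empty_and_monotone(merged_with_phenotypes):
    assert manifestations(merged_with_phenotypes,
                          fx.TROCHANTER_SIZE) == set()
    # adding a new abnormality subclass can only grow the result
    from eqtraits.model import Curie, SubClassOf
    grown = merged_with_phenotypes.copy()
    new = Curie("MP", "0099999")
    grown.add_term(new, "borderline microcephaly")
    grown.add_axiom(SubClassOf(Named(new), Named(fx.MICROCEPHALY)))
    states = manifestations(grown, fx.HEAD_CIRCUMFERENCE)
    assert states >= {fx.DECREASED_HEAD_CIRCUMFERENCE, fx.MICROCEPHALY,
                      fx.PROGRESSIVE_MICROCEPHALY, new}


def test_manifestations_unknown_attribute(merged_with_phenotypes):
    from eqtraits.model import Curie, OntologyError
    with pytest.raises(OntologyError):
        manifestations(merged_with_phenotypes, Curie("OBA", "404"))
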