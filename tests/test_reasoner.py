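"""EL saturation reasoner: worked examples, properties, oracle agreement."""

import random

import pytest

from eqtraits import fixtures as fx
from eqtraits.model import (And, Curie, Named, Ontology, RoleChain, Some,
                            SubClassOf, TOP)
from eqtraits.oracle import brute_force_subsumers
from eqtraits.reasoner import classify, entails, query_named_subclasses


def _named(tag):
    return Named(Curie("TST", tag))


def test_empty_ontology_is_reflexive_with_top():
    ont = Ontology()
    a, b = Curie("TST", "A"), Curie("TST", "B")
    ont.add_term(a)
    ont.add_term(b)
    result = classify(ont)
    assert result.subsumers[a] == {a, TOP.id}
    assert result.subsumers[b] == {b, TOP.id}


def test_told_chain_and_transitivity():
    ont = Ontology()
    for tag in "ABC":
        ont.add_term(Curie("TST", tag))
    ont.add_axiom(SubClassOf(_named("A"), _named("B")))
    ont.add_axiom(SubClassOf(_named("B"), _named("C")))
    result = classify(ont)
    assert Curie("TST", "C") in result.subsumers[Curie("TST", "A")]
    assert result.direct_parents[Curie("TST", "A")] == {Curie("TST", "B")}


def test_chemical_hierarchy_propagates_into_traits(release_result):
    """A trait on lysine classifies under the same trait on amino acid
    purely because of the chemical reference hierarchy."""
    assert release_result.is_subsumed(fx.BLOOD_LYSINE_AMOUNT,
                                      fx.BLOOD_AMINO_ACID_AMOUNT)
    assert not release_result.is_subsumed(fx.BLOOD_GLUCOSE_AMOUNT,
                                          fx.BLOOD_AMINO_ACID_AMOUNT)


def test_abnormal_state_classifies_under_neutral_trait(
        merged_with_phenotypes):
    result = classify(merged_with_phenotypes)
    assert result.is_subsumed(fx.HYPOLYSINEMIA, fx.BLOOD_LYSINE_AMOUNT)
    assert result.is_subsumed(fx.HYPOLYSINEMIA, fx.BLOOD_AMINO_ACID_AMOUNT)
    # the neutral trait is not subsumed by the abnormal state
    assert not result.is_subsumed(fx.BLOOD_LYSINE_AMOUNT, fx.HYPOLYSINEMIA)


def test_role_chain_entailment():
    """characteristic_of o part_of => characteristic_of_part_of."""
    ont = Ontology()
    for tag in ("C", "X", "Y"):
        ont.add_term(Curie("TST", tag))
    co, po, cpo = (Curie("TST", t) for t in ("co", "po", "cpo"))
    for role in (co, po, cpo):
        ont.add_role(role)
    ont.add_axiom(RoleChain(co, po, cpo))
    ont.add_axiom(SubClassOf(_named("C"), Some(co, _named("X"))))
    ont.add_axiom(SubClassOf(_named("X"), Some(po, _named("Y"))))
    assert entails(ont, _named("C"), Some(cpo, _named("Y")))
    assert not entails(ont, _named("C"), Some(cpo, _named("X")))


def test_dl_query_returns_exact_cardiovascular_set(release):
    query = And((Named(fx.MORPHOLOGY),
                 Some(fx.CHARACTERISTIC_OF_PART_OF,
                      Named(fx.CARDIOVASCULAR_SYSTEM))))
    hits = query_named_subclasses(release, query)
    assert hits == {fx.HEART_MORPHOLOGY, fx.AORTA_MORPHOLOGY}


def test_query_top_returns_all_live_classes(release):
    hits = query_named_subclasses(release, TOP)
    assert hits == set(release.live_terms())
    assert query_named_subclasses(Ontology(), TOP) == set()


def test_entails_top_always():
    ont = Ontology()
    ont.add_term(Curie("TST", "A"))
    assert entails(ont, _named("A"), TOP)


@pytest.mark.parametrize("seed", range(30))
def test_monotonicity_under_axiom_addition(seed):
    """Adding axioms never removes entailed subsumptions."""
    rng = random.Random(seed)
    ont = fx.random_el_ontology(seed, n_classes=10, n_roles=2, n_axioms=15)
    before = classify(ont).subsumers
    more = fx.random_el_ontology(seed + 1000, n_classes=10, n_roles=2,
                                 n_axioms=8)
    grown = ont.copy()
    for ax in more.axioms:
        grown.add_axiom(ax)
    after = classify(grown).subsumers
    for cid, subs in before.items():
        assert subs <= after[cid], f"lost subsumers for {cid}"


@pytest.mark.parametrize("seed", range(40))
def test_reasoner_matches_brute_force_oracle(seed):
    """Spot sample of the oracle-equivalence suite (the full 200-seed run
    lives in the acceptance tests)."""
    rng = random.Random(seed * 7919)
    ont = fx.random_el_ontology(seed,
                                n_classes=rng.randint(5, 25),
                                n_roles=rng.randint(1, 3),
                                n_axioms=rng.randint(10, 60))
    assert classify(ont).subsumers == brute_force_subsumers(ont).subsumers


def test_direct_parents_is_transitive_reduction(release_result):
    for child, parents in release_result.direct_parents.items():
        for p in parents:
            assert release_result.is_subsumed(child, p)
        # distinct (non-equivalent) parents are incomparable
        for p in parents:
            for q in parents:
                if not release_result.is_subsumed(p, q) \
                        or not release_result.is_subsumed(q, p):
                    assert not release_result.strictly_subsumed(p, q)


def test_equivalence_partition_contains_root_and_characteristic(
        release_result):
    group = release_result.equivalents(fx.TRAIT_ROOT)
    assert fx.CHARACTERISTIC in group
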