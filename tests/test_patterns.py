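"""Pattern loading, row/table compilation and trait-candidate derivation."""

import pytest

from eqtraits import fixtures as fx
from eqtraits.manchester import parse_class_expression
from eqtraits.model import (And, Curie, EquivalentTo, IdMinter, Named, Some,
                            SubClassOf, canonicalize)
from eqtraits.patterns import (CompileError, FillerRow, PatternError,
                               compile_row, compile_table,
                               derive_trait_candidates, load_filler_table,
                               load_pattern)
from eqtraits.reasoner import classify, entails


def test_load_pattern_declares_vars(bundle):
    pattern = bundle.pattern_by_id("entity-attribute")
    assert list(pattern.vars) == ["attribute", "entity"]
    assert len(pattern.gci_templates) == 1


def test_load_pattern_arity_mismatch_is_rejected():
    bad = fx.ENTITY_ATTRIBUTE_PATTERN.replace(
        'text: "%s %s"\n  vars: [entity, attribute]',
        'text: "%s %s %s"\n  vars: [entity, attribute]')
    with pytest.raises(PatternError):
        load_pattern(bad)


def test_load_pattern_undeclared_var_is_rejected():
    bad = fx.ENTITY_ATTRIBUTE_PATTERN.replace("[entity, attribute]",
                                              "[entity, wrongvar]", 1)
    with pytest.raises(PatternError, match="wrongvar"):
        load_pattern(bad)


def test_compile_row_trochanter_size(bundle, refs):
    pattern = bundle.pattern_by_id("entity-attribute")
    row = FillerRow(fx.TROCHANTER_SIZE,
                    {"attribute": fx.SIZE, "entity": fx.TROCHANTER})
    record, axioms = compile_row(pattern, row, refs)
    assert record.label == "trochanter size"
    assert record.definition == "The size of trochanter."
    equiv = [ax for ax in axioms if isinstance(ax, EquivalentTo)]
    assert len(equiv) == 1
    expected = canonicalize(And((Named(fx.SIZE),
                                 Some(fx.CHARACTERISTIC_OF,
                                      Named(fx.TROCHANTER)))))
    assert canonicalize(equiv[0].expr) == expected


def test_compile_row_blood_glucose_amount(bundle, refs):
    pattern = bundle.pattern_by_id("chemical-in-entity-attribute")
    row = FillerRow(fx.BLOOD_GLUCOSE_AMOUNT,
                    {"attribute": fx.AMOUNT, "chemical": fx.GLUCOSE,
                     "location": fx.BLOOD})
    record, axioms = compile_row(pattern, row, refs)
    assert record.label == "blood glucose amount"
    equiv = canonicalize(axioms[0].expr)
    expected = canonicalize(parse_class_expression(
        "PATO:0000070 and (RO:0000052 some "
        "(CHEBI:17234 and (BFO:0000050 some UBERON:0000178)))"))
    assert equiv == expected


def test_compile_row_role_pattern_uses_has_role(bundle, refs):
    pattern = bundle.pattern_by_id("role-attribute")
    row = FillerRow(fx.SERUM_METABOLITE_AMOUNT,
                    {"attribute": fx.AMOUNT,
                     "role": fx.SERUM_METABOLITE_ROLE})
    record, axioms = compile_row(pattern, row, refs)
    assert record.label == "serum metabolite amount"
    # the logical definition must reference the chemical role via has_role
    from eqtraits.model import expr_signature, subexpressions
    assert fx.HAS_ROLE in expr_signature(axioms[0].expr)
    assert Some(fx.HAS_ROLE, Named(fx.SERUM_METABOLITE_ROLE)) in \
        set(subexpressions(canonicalize(axioms[0].expr)))


def test_compile_row_range_violation(bundle, refs):
    pattern = bundle.pattern_by_id("chemical-in-entity-attribute")
    row = FillerRow(Curie("OBA", "9999991"),
                    {"attribute": fx.AMOUNT, "chemical": fx.BLOOD,
                     "location": fx.BLOOD})  # blood is not a chemical
    with pytest.raises(PatternError, match="range"):
        compile_row(pattern, row, refs)


def test_compile_table_counts_and_gcis(bundle, refs):
    pattern = bundle.pattern_by_id("entity-attribute")
    rows = bundle.tables["entity-attribute"]
    fragment = compile_table(pattern, rows, refs)
    equivs = [ax for ax in fragment.axioms
              if isinstance(ax, EquivalentTo)]
    gcis = [ax for ax in fragment.axioms
            if isinstance(ax, SubClassOf) and not isinstance(ax.sub, Named)]
    assert len(equivs) == len(rows)
    assert len(gcis) == len(rows)
    for row in rows:
        assert fragment.terms[row.defined_class].label
        assert fragment.terms[row.defined_class].definition


def test_compile_table_duplicate_defined_class_names_both_rows(bundle, refs):
    pattern = bundle.pattern_by_id("entity-attribute")
    rows = [
        FillerRow(fx.HEAD_SIZE, {"attribute": fx.SIZE, "entity": fx.HEAD}),
        FillerRow(fx.EYE_SIZE, {"attribute": fx.SIZE, "entity": fx.EYE}),
        FillerRow(fx.HEAD_SIZE, {"attribute": fx.SIZE, "entity": fx.HEAD}),
    ]
    with pytest.raises(CompileError, match="rows 1 and 3"):
        compile_table(pattern, rows, refs)


def test_compile_table_aggregates_errors(bundle, refs):
    pattern = bundle.pattern_by_id("entity-attribute")
    rows = [
        FillerRow(Curie("OBA", "9999992"),
                  {"attribute": fx.SIZE, "entity": Curie("UBERON", "404")}),
        FillerRow(Curie("OBA", "9999993"),
                  {"attribute": fx.HEAD, "entity": fx.HEAD}),
    ]
    with pytest.raises(CompileError) as excinfo:
        compile_table(pattern, rows, refs)
    assert len(excinfo.value.errors) == 2


def test_no_asserted_subclass_between_compiled_terms(traits):
    compiled = {c for c in traits.terms if traits.equiv_for(c) is not None}
    for ax in traits.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) \
                and isinstance(ax.sup, Named):
            assert not (ax.sub.id in compiled and ax.sup.id in compiled)


def test_gci_mereology_contract(release):
    """For every compiled pair T(E,Q), T(E',Q) with E part_of E', the
    classified ontology entails T(E,Q) SubClassOf part_of some T(E',Q)."""
    assert entails(release, Named(fx.ULNA_SIZE),
                   Some(fx.PART_OF, Named(fx.FORELIMB_SKELETON_SIZE)))
    assert entails(release, Named(fx.EYE_SIZE),
                   Some(fx.PART_OF, Named(fx.HEAD_SIZE)))


def test_filler_table_tsv_round_trip(bundle):
    pattern = bundle.pattern_by_id("entity-attribute")
    tsv = "defined_class\tattribute\tentity\n" \
          f"{fx.HEAD_SIZE}\t{fx.SIZE}\t{fx.HEAD}\n"
    rows = load_filler_table(tsv, pattern)
    assert rows == [FillerRow(fx.HEAD_SIZE,
                              {"attribute": fx.SIZE, "entity": fx.HEAD})]
    with pytest.raises(PatternError, match="missing columns"):
        load_filler_table("defined_class\tattribute\nX:1\tY:2\n", pattern)


def test_derive_trait_candidates_from_phenotype_definitions(bundle):
    rows, skipped = derive_trait_candidates(
        bundle.mini_phenotype, bundle.mini_characteristics,
        fx.CHARACTERISTIC_OF, minter=IdMinter(start=9100001))
    # decomposable: the four classes whose entity filler is a named class
    bindings = {(str(r.bindings["attribute"]), str(r.bindings["entity"]))
                for r in rows}
    assert len(rows) == 4
    assert all(r.needs_review for r in rows)
    assert (str(fx.CIRCUMFERENCE), str(fx.HEAD)) in bindings
    assert (str(fx.SIZE), str(fx.BRAIN_VENTRICLE)) in bindings
    # complex fillers and classes without an EQ definition are skipped
    assert fx.HYPOLYSINEMIA in skipped
    assert fx.ABNORMAL_GAIT in skipped
    # skipped: 2 complex-filler classes, 2 classes without an EQ
    # definition, plus the phenotype root
    assert len(skipped) == 5


def test_nearest_attribute_ancestor_is_most_specific(bundle):
    """'severely decreased circumference' resolves to 'circumference',
    not the more general 'size'."""
    rows, _ = derive_trait_candidates(
        bundle.mini_phenotype, bundle.mini_characteristics,
        fx.CHARACTERISTIC_OF)
    micro_rows = [r for r in rows if r.bindings["entity"] == fx.HEAD]
    assert micro_rows
    assert all(r.bindings["attribute"] == fx.CIRCUMFERENCE
               for r in micro_rows)
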