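"""Deterministic generators for all test inputs.

Everything the test suite needs is generated programmatically here: small
curated reference ontologies (a mini anatomy with part-of structure, a mini
chemical hierarchy, a mini characteristics/qualities hierarchy), a mini
phenotype ontology of EQ-defined abnormality classes, the pattern templates
with their filler tables, seeded random EL ontologies for oracle-equivalence
testing, and QC defect injectors.  The brute-force reasoning oracle lives in
:mod:`eqtraits.oracle` so that it shares no saturation code with the
reasoner.

The mini ontologies stand in for Uberon/ChEBI/PATO/MP extracts: identifiers
reuse the familiar reference-ontology CURIEs where the worked examples use
them (trochanter, blood, lysine, amount, …) but the content is a synthetic,
self-contained fragment.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (And, Curie, EquivalentTo, IdMinter, Named, Ontology,
                    OntologyError, OBSOLETE_PREFIX, RoleChain, Some,
                    SubClassOf, SubRoleOf, default_prefixes)
from .patterns import FillerRow, Pattern, load_pattern

# Roles shared by the fixtures.
PART_OF = Curie("BFO", "0000050")
CHARACTERISTIC_OF = Curie("RO", "0000052")
CHARACTERISTIC_OF_PART_OF = Curie("RO", "0002314")
HAS_ROLE = Curie("RO", "0000087")
HAS_MODIFIER = Curie("RO", "0002573")

# Anatomy
ANATOMICAL_ENTITY = Curie("UBERON", "0001062")
TROCHANTER = Curie("UBERON", "0000980")
BLOOD = Curie("UBERON", "0000178")
HEAD = Curie("UBERON", "0000033")
EYE = Curie("UBERON", "0000970")
ULNA = Curie("UBERON", "0001424")
FORELIMB_SKELETON = Curie("UBERON", "0001440")
HEART = Curie("UBERON", "0000948")
AORTA = Curie("UBERON", "0000947")
CARDIOVASCULAR_SYSTEM = Curie("UBERON", "0004535")
BRAIN = Curie("UBERON", "0000955")
BRAIN_VENTRICLE = Curie("UBERON", "0004086")

# Chemistry
CHEMICAL_ENTITY = Curie("CHEBI", "24431")
AMINO_ACID = Curie("CHEBI", "33709")
LYSINE = Curie("CHEBI", "25094")
GLUCOSE = Curie("CHEBI", "17234")
CHEMICAL_ROLE = Curie("CHEBI", "50906")
METABOLITE_ROLE = Curie("CHEBI", "25212")
SERUM_METABOLITE_ROLE = Curie("CHEBI", "91007")

# Characteristics
CHARACTERISTIC = Curie("PATO", "0000001")
SIZE = Curie("PATO", "0000117")
MORPHOLOGY = Curie("PATO", "0000051")
AMOUNT = Curie("PATO", "0000070")
CIRCUMFERENCE = Curie("PATO", "0000934")
DECREASED_AMOUNT = Curie("PATO", "0001997")
INCREASED_AMOUNT = Curie("PATO", "0000470")
DECREASED_SIZE = Curie("PATO", "0000587")
INCREASED_SIZE = Curie("PATO", "0000586")
DECREASED_CIRCUMFERENCE = Curie("PATO", "0005905")
SEVERELY_DECREASED_CIRCUMFERENCE = Curie("PATO", "0005906")
ABNORMAL = Curie("PATO", "0000460")
PROGRESSIVE = Curie("PATO", "0001818")

ATTRIBUTE_SUBSET = "attribute_slim"

# Trait terms
TRAIT_ROOT = Curie("OBA", "0000001")
TROCHANTER_SIZE = Curie("OBA", "0002360")
HEAD_SIZE = Curie("OBA", "1000001")
EYE_SIZE = Curie("OBA", "1000002")
ULNA_SIZE = Curie("OBA", "1000003")
FORELIMB_SKELETON_SIZE = Curie("OBA", "1000004")
BRAIN_VENTRICLE_SIZE = Curie("OBA", "0002294")
HEART_MORPHOLOGY = Curie("OBA", "1000005")
AORTA_MORPHOLOGY = Curie("OBA", "1000006")
HEAD_MORPHOLOGY = Curie("OBA", "1000007")
HEAD_CIRCUMFERENCE = Curie("OBA", "VT0000047")
BLOOD_GLUCOSE_AMOUNT = Curie("OBA", "VT0000188")
BLOOD_LYSINE_AMOUNT = Curie("OBA", "2020005")
BLOOD_AMINO_ACID_AMOUNT = Curie("OBA", "2020050")
SERUM_METABOLITE_AMOUNT = Curie("OBA", "2050092")

# Phenotype terms (abnormality states)
PHENO_ROOT = Curie("MP", "0000001")
HYPOLYSINEMIA = Curie("MP", "0030719")
HYPERGLYCEMIA = Curie("MP", "0005559")
DECREASED_HEAD_CIRCUMFERENCE = Curie("MP", "0040195")
MICROCEPHALY = Curie("MP", "0000252")
PROGRESSIVE_MICROCEPHALY = Curie("MP", "0000253")
VENTRICULOMEGALY = Curie("MP", "0002119")
ABNORMAL_GAIT = Curie("MP", "0001406")
PREWEANING_LETHALITY = Curie("MP", "0011085")


ENTITY_ATTRIBUTE_PATTERN = """\
pattern_id: entity-attribute
vars:
  attribute: PATO:0000001
  entity: owl:Thing
relations:
  characteristic_of: RO:0000052
  part_of: BFO:0000050
name:
  text: "%s %s"
  vars: [entity, attribute]
definition:
  text: "The %s of %s."
  vars: [attribute, entity]
synonyms:
  - text: "%s of %s"
    vars: [attribute, entity]
equivalent_to:
  text: "%s and (RO:0000052 some %s)"
  vars: [attribute, entity]
gcis:
  - sub:
      text: "%s and (RO:0000052 some (BFO:0000050 some %s))"
      vars: [attribute, entity]
    sup:
      text: "BFO:0000050 some (%s and (RO:0000052 some %s))"
      vars: [attribute, entity]
"""

CHEMICAL_IN_ENTITY_PATTERN = """\
pattern_id: chemical-in-entity-attribute
vars:
  attribute: PATO:0000001
  chemical: CHEBI:24431
  location: UBERON:0001062
relations:
  characteristic_of: RO:0000052
  part_of: BFO:0000050
name:
  text: "%s %s %s"
  vars: [location, chemical, attribute]
definition:
  text: "The %s of %s in the %s."
  vars: [attribute, chemical, location]
equivalent_to:
  text: "%s and (RO:0000052 some (%s and (BFO:0000050 some %s)))"
  vars: [attribute, chemical, location]
"""

ROLE_ATTRIBUTE_PATTERN = """\
pattern_id: role-attribute
vars:
  attribute: PATO:0000001
  role: CHEBI:50906
relations:
  characteristic_of: RO:0000052
  has_role: RO:0000087
name:
  text: "%s %s"
  vars: [role, attribute]
definition:
  text: "The %s of entities bearing the %s role."
  vars: [attribute, role]
equivalent_to:
  text: "%s and (RO:0000052 some (RO:0000087 some %s))"
  vars: [attribute, role]
"""

ABNORMALITY_PATTERN = """\
pattern_id: abnormality
vars:
  state: PATO:0000001
  entity: owl:Thing
relations:
  characteristic_of: RO:0000052
  has_modifier: RO:0002573
name:
  text: "abnormal %s %s"
  vars: [entity, state]
definition:
  text: "An abnormal %s of %s."
  vars: [state, entity]
equivalent_to:
  text: "%s and (RO:0000052 some %s) and (RO:0002573 some PATO:0000460)"
  vars: [state, entity]
"""


@dataclass
class FixtureBundle:
    """Fixed-content bundle of fixture ontologies, patterns and tables."""

    mini_anatomy: Ontology
    mini_chemical: Ontology
    mini_characteristics: Ontology
    mini_phenotype: Ontology
    patterns: list[Pattern]
    tables: dict[str, list[FillerRow]]
    roles: Ontology = field(default=None)  # role declarations and axioms

    def reference_ontology(self) -> Ontology:
        """Anatomy + chemical + characteristics + role axioms, merged."""
        merged = self.mini_anatomy.merge(self.mini_chemical)
        merged = merged.merge(self.mini_characteristics)
        return merged.merge(self.roles)

    def pattern_by_id(self, pattern_id: str) -> Pattern:
        for p in self.patterns:
            if p.pattern_id == pattern_id:
                return p
        raise KeyError(pattern_id)


def _roles_ontology() -> Ontology:
    ont = Ontology()
    ont.add_role(PART_OF, "part of")
    ont.add_role(CHARACTERISTIC_OF, "characteristic of")
    ont.add_role(CHARACTERISTIC_OF_PART_OF, "characteristic of part of")
    ont.add_role(HAS_ROLE, "has role")
    ont.add_role(HAS_MODIFIER, "has modifier")
    ont.add_axiom(RoleChain(PART_OF, PART_OF, PART_OF))
    ont.add_axiom(RoleChain(CHARACTERISTIC_OF, PART_OF,
                            CHARACTERISTIC_OF_PART_OF))
    return ont


def _mini_anatomy() -> Ontology:
    ont = Ontology()
    ont.add_role(PART_OF, "part of")
    ont.add_axiom(RoleChain(PART_OF, PART_OF, PART_OF))
    terms = {
        ANATOMICAL_ENTITY: "anatomical entity",
        TROCHANTER: "trochanter",
        BLOOD: "blood",
        HEAD: "head",
        EYE: "eye",
        ULNA: "ulna",
        FORELIMB_SKELETON: "forelimb skeleton",
        HEART: "heart",
        AORTA: "aorta",
        CARDIOVASCULAR_SYSTEM: "cardiovascular system",
        BRAIN: "brain",
        BRAIN_VENTRICLE: "brain ventricle",
    }
    for cid, label in terms.items():
        ont.add_term(cid, label)
        if cid != ANATOMICAL_ENTITY:
            ont.add_axiom(SubClassOf(Named(cid), Named(ANATOMICAL_ENTITY)))
    for part, whole in ((EYE, HEAD), (ULNA, FORELIMB_SKELETON),
                        (HEART, CARDIOVASCULAR_SYSTEM),
                        (AORTA, CARDIOVASCULAR_SYSTEM),
                        (BRAIN, HEAD), (BRAIN_VENTRICLE, BRAIN)):
        ont.add_axiom(SubClassOf(Named(part), Some(PART_OF, Named(whole))))
    return ont


def _mini_chemical() -> Ontology:
    ont = Ontology()
    ont.add_role(HAS_ROLE, "has role")
    terms = {
        CHEMICAL_ENTITY: "chemical entity",
        AMINO_ACID: "amino acid",
        LYSINE: "lysine",
        GLUCOSE: "glucose",
        CHEMICAL_ROLE: "chemical role",
        METABOLITE_ROLE: "metabolite",
        SERUM_METABOLITE_ROLE: "serum metabolite",
    }
    for cid, label in terms.items():
        ont.add_term(cid, label)
    for sub, sup in ((AMINO_ACID, CHEMICAL_ENTITY), (LYSINE, AMINO_ACID),
                     (GLUCOSE, CHEMICAL_ENTITY),
                     (METABOLITE_ROLE, CHEMICAL_ROLE),
                     (SERUM_METABOLITE_ROLE, METABOLITE_ROLE)):
        ont.add_axiom(SubClassOf(Named(sub), Named(sup)))
    return ont


def _mini_characteristics() -> Ontology:
    ont = Ontology()
    terms = {
        CHARACTERISTIC: "characteristic",
        SIZE: "size",
        MORPHOLOGY: "morphology",
        AMOUNT: "amount",
        CIRCUMFERENCE: "circumference",
        DECREASED_AMOUNT: "decreased amount",
        INCREASED_AMOUNT: "increased amount",
        DECREASED_SIZE: "decreased size",
        INCREASED_SIZE: "increased size",
        DECREASED_CIRCUMFERENCE: "decreased circumference",
        SEVERELY_DECREASED_CIRCUMFERENCE: "severely decreased circumference",
        ABNORMAL: "abnormal",
        PROGRESSIVE: "progressive",
    }
    for cid, label in terms.items():
        ont.add_term(cid, label)
    for sub, sup in ((SIZE, CHARACTERISTIC), (MORPHOLOGY, CHARACTERISTIC),
                     (AMOUNT, CHARACTERISTIC), (CIRCUMFERENCE, SIZE),
                     (DECREASED_AMOUNT, AMOUNT), (INCREASED_AMOUNT, AMOUNT),
                     (DECREASED_SIZE, SIZE), (INCREASED_SIZE, SIZE),
                     (DECREASED_CIRCUMFERENCE, CIRCUMFERENCE),
                     (SEVERELY_DECREASED_CIRCUMFERENCE,
                      DECREASED_CIRCUMFERENCE),
                     (ABNORMAL, CHARACTERISTIC),
                     (PROGRESSIVE, CHARACTERISTIC)):
        ont.add_axiom(SubClassOf(Named(sub), Named(sup)))
    ont.subsets[ATTRIBUTE_SUBSET] = {SIZE, MORPHOLOGY, AMOUNT, CIRCUMFERENCE}
    return ont


def _abnormality(state: Curie, entity_expr) -> And:
    return And((Named(state), Some(CHARACTERISTIC_OF, entity_expr),
                Some(HAS_MODIFIER, Named(ABNORMAL))))


def _mini_phenotype() -> Ontology:
    ont = Ontology()
    for role, label in ((CHARACTERISTIC_OF, "characteristic of"),
                        (PART_OF, "part of"), (HAS_MODIFIER, "has modifier")):
        ont.add_role(role, label)
    ont.add_term(PHENO_ROOT, "phenotypic abnormality")
    defs: dict[Curie, tuple[str, And | None]] = {
        HYPOLYSINEMIA: (
            "decreased circulating lysine level",
            _abnormality(DECREASED_AMOUNT,
                         And((Named(LYSINE),
                              Some(PART_OF, Named(BLOOD)))))),
        HYPERGLYCEMIA: (
            "increased circulating glucose level",
            _abnormality(INCREASED_AMOUNT,
                         And((Named(GLUCOSE),
                              Some(PART_OF, Named(BLOOD)))))),
        DECREASED_HEAD_CIRCUMFERENCE: (
            "decreased head circumference",
            _abnormality(DECREASED_CIRCUMFERENCE, Named(HEAD))),
        MICROCEPHALY: (
            "microcephaly",
            _abnormality(SEVERELY_DECREASED_CIRCUMFERENCE, Named(HEAD))),
        PROGRESSIVE_MICROCEPHALY: (
            "progressive microcephaly",
            And((Named(SEVERELY_DECREASED_CIRCUMFERENCE),
                 Some(CHARACTERISTIC_OF, Named(HEAD)),
                 Some(HAS_MODIFIER, Named(ABNORMAL)),
                 Some(HAS_MODIFIER, Named(PROGRESSIVE))))),
        VENTRICULOMEGALY: (
            "ventriculomegaly",
            _abnormality(INCREASED_SIZE, Named(BRAIN_VENTRICLE))),
        ABNORMAL_GAIT: ("abnormal gait", None),
        PREWEANING_LETHALITY: ("preweaning lethality", None),
    }
    for cid, (label, equiv) in defs.items():
        ont.add_term(cid, label)
        ont.add_axiom(SubClassOf(Named(cid), Named(PHENO_ROOT)))
        if equiv is not None:
            ont.add_axiom(EquivalentTo(cid, equiv))
    return ont


def _trait_tables() -> dict[str, list[FillerRow]]:
    ea = [
        FillerRow(TROCHANTER_SIZE, {"attribute": SIZE, "entity": TROCHANTER}),
        FillerRow(HEAD_SIZE, {"attribute": SIZE, "entity": HEAD}),
        FillerRow(EYE_SIZE, {"attribute": SIZE, "entity": EYE}),
        FillerRow(ULNA_SIZE, {"attribute": SIZE, "entity": ULNA}),
        FillerRow(FORELIMB_SKELETON_SIZE,
                  {"attribute": SIZE, "entity": FORELIMB_SKELETON}),
        FillerRow(BRAIN_VENTRICLE_SIZE,
                  {"attribute": SIZE, "entity": BRAIN_VENTRICLE}),
        FillerRow(HEART_MORPHOLOGY,
                  {"attribute": MORPHOLOGY, "entity": HEART}),
        FillerRow(AORTA_MORPHOLOGY,
                  {"attribute": MORPHOLOGY, "entity": AORTA}),
        FillerRow(HEAD_MORPHOLOGY,
                  {"attribute": MORPHOLOGY, "entity": HEAD}),
        FillerRow(HEAD_CIRCUMFERENCE,
                  {"attribute": CIRCUMFERENCE, "entity": HEAD}),
    ]
    chem = [
        FillerRow(BLOOD_GLUCOSE_AMOUNT,
                  {"attribute": AMOUNT, "chemical": GLUCOSE,
                   "location": BLOOD}),
        FillerRow(BLOOD_LYSINE_AMOUNT,
                  {"attribute": AMOUNT, "chemical": LYSINE,
                   "location": BLOOD}),
        FillerRow(BLOOD_AMINO_ACID_AMOUNT,
                  {"attribute": AMOUNT, "chemical": AMINO_ACID,
                   "location": BLOOD}),
    ]
    role = [
        FillerRow(SERUM_METABOLITE_AMOUNT,
                  {"attribute": AMOUNT, "role": SERUM_METABOLITE_ROLE}),
    ]
    return {"entity-attribute": ea, "chemical-in-entity-attribute": chem,
            "role-attribute": role}


def build_fixture_bundle() -> FixtureBundle:
    """Build the fixed-content fixture bundle.  Byte-identical across runs
    (no randomness is involved)."""
    patterns = [load_pattern(ENTITY_ATTRIBUTE_PATTERN),
                load_pattern(CHEMICAL_IN_ENTITY_PATTERN),
                load_pattern(ROLE_ATTRIBUTE_PATTERN),
                load_pattern(ABNORMALITY_PATTERN)]
    return FixtureBundle(
        mini_anatomy=_mini_anatomy(),
        mini_chemical=_mini_chemical(),
        mini_characteristics=_mini_characteristics(),
        mini_phenotype=_mini_phenotype(),
        patterns=patterns,
        tables=_trait_tables(),
        roles=_roles_ontology(),
    )


def compile_bundle_traits(bundle: FixtureBundle) -> Ontology:
    """Compile all fixture filler tables into one trait ontology fragment,
    including the trait root ("biological attribute", equivalent to the
    characteristics root so that every compiled trait classifies under it)."""
    from .patterns import compile_table
    from .reasoner import classify

    refs = bundle.reference_ontology()
    refs_result = classify(refs)
    merged = Ontology(prefixes=dict(refs.prefixes))
    for pattern_id, rows in sorted(bundle.tables.items()):
        pattern = bundle.pattern_by_id(pattern_id)
        fragment = compile_table(pattern, rows, refs, refs_result)
        merged = merged.merge(fragment)
    merged.add_term(TRAIT_ROOT, "biological attribute",
                    definition="A characteristic of a biological entity.")
    merged.add_axiom(EquivalentTo(TRAIT_ROOT, Named(CHARACTERISTIC)))
    if CHARACTERISTIC not in merged.terms:
        merged.add_term(CHARACTERISTIC, "characteristic")
    return merged


def external_vocabulary() -> Ontology:
    """A mini external trait vocabulary (VT-style: plain labels, no logic).

    Eight labels normalise onto compiled trait labels (several only after
    stop-word removal or via an exact synonym), one decomposes against the
    references, and one matches nothing.
    """
    ont = Ontology()
    labels = {
        Curie("VT", "0000001"): "head size trait",
        Curie("VT", "0000002"): "eye size",
        Curie("VT", "0000003"): "ulna size measurement",
        Curie("VT", "0000004"): "heart morphology trait",
        Curie("VT", "0000005"): "aorta morphology",
        Curie("VT", "0000006"): "brain ventricle size",
        Curie("VT", "0000007"): "head circumference trait",
        Curie("VT", "0000008"): "blood glucose level",
        Curie("VT", "0000009"): "lysine measurement",
        Curie("VT", "0000010"): "xyzzy level",
    }
    for cid, label in labels.items():
        ont.add_term(cid, label)
    # the external 'blood glucose level' carries an exact synonym that
    # normalises onto the compiled trait label
    ont.terms[Curie("VT", "0000008")].synonyms.append(
        ("blood glucose amount", "EXACT"))
    return ont


# --------------------------------------------------------------------------
# Random EL ontologies for oracle-equivalence testing
# --------------------------------------------------------------------------


def random_el_ontology(seed: int, n_classes: int = 15, n_roles: int = 3,
                       n_axioms: int = 40) -> Ontology:
    """Seeded random ontology inside the supported fragment.

    Axiom mix: told subsumptions, existential right-hand sides, small
    conjunction sides, occasional GCI left-hand sides, role hierarchy and
    role chains.  All existential fillers are drawn from the declared class
    set, which keeps the subexpression closure (and hence the naive oracle)
    bounded.
    """
    if n_classes <= 0 or n_axioms <= 0 or not 1 <= n_roles <= 3:
        raise OntologyError("sizes must be positive and n_roles <= 3")
    rng = random.Random(seed)
    ont = Ontology()
    classes = [Curie("TST", f"C{i:03d}") for i in range(n_classes)]
    roles = [Curie("TST", f"r{i}") for i in range(n_roles)]
    for c in classes:
        ont.add_term(c, f"class {c.local}")
    for r in roles:
        ont.add_role(r, f"role {r.local}")

    def named() -> Named:
        return Named(rng.choice(classes))

    def small_conj() -> And:
        a, b = rng.sample(classes, 2)
        return And((Named(a), Named(b)))

    def existential() -> Some:
        return Some(rng.choice(roles), named())

    has_equiv: set[Curie] = set()
    kinds = ("sub_nn", "sub_n_ex", "gci_ex_n", "gci_conj_n", "sub_n_conj",
             "equiv", "role_sub", "role_chain")
    weights = (30, 20, 12, 12, 8, 8, 5, 5)
    for _ in range(n_axioms):
        kind = rng.choices(kinds, weights)[0]
        if kind == "sub_nn":
            ont.add_axiom(SubClassOf(named(), named()))
        elif kind == "sub_n_ex":
            ont.add_axiom(SubClassOf(named(), existential()))
        elif kind == "gci_ex_n":
            ont.add_axiom(SubClassOf(existential(), named()))
        elif kind == "gci_conj_n":
            ont.add_axiom(SubClassOf(small_conj(), named()))
        elif kind == "sub_n_conj":
            ont.add_axiom(SubClassOf(named(), small_conj()))
        elif kind == "equiv":
            target = rng.choice(classes)
            if target in has_equiv:
                ont.add_axiom(SubClassOf(named(), named()))
                continue
            has_equiv.add(target)
            expr = rng.choice((small_conj(), existential(),
                               And((Named(rng.choice(classes)),
                                    existential()))))
            ont.add_axiom(EquivalentTo(target, expr))
        elif kind == "role_sub":
            sub, sup = rng.choice(roles), rng.choice(roles)
            ont.add_axiom(SubRoleOf(sub, sup))
        else:
            ont.add_axiom(RoleChain(rng.choice(roles), rng.choice(roles),
                                    rng.choice(roles)))
    return ont


# --------------------------------------------------------------------------
# QC defect injection
# --------------------------------------------------------------------------

DEFECT_IDS = ("duplicate_definition", "orphan_term", "obsolete_with_axioms",
              "dangling_ref", "accidental_equivalence")


def inject_defect(ont: Ontology, defect: str, seed: int = 0) -> Ontology:
    """Return a copy of a compiled trait ontology with exactly one seeded
    violation of the named kind; the input is left untouched."""
    rng = random.Random(seed)
    out = ont.copy()
    compiled = sorted(
        (c for c in out.live_terms()
         if c.prefix == "OBA" and c != TRAIT_ROOT
         and out.equiv_for(c) is not None), key=str)
    if defect == "duplicate_definition":
        victim = rng.choice(compiled)
        equiv = out.equiv_for(victim)
        dup = Curie("OBA", "9900001")
        out.add_term(dup, out.terms[victim].label + " (duplicate)")
        out.add_axiom(EquivalentTo(dup, equiv.expr))
    elif defect == "orphan_term":
        orphan = Curie("OBA", "9900002")
        out.add_term(orphan, "stray attribute")
    elif defect == "obsolete_with_axioms":
        victim = rng.choice(compiled)
        rec = out.terms[victim]
        rec.deprecated = True
        rec.label = OBSOLETE_PREFIX + rec.label
        # logical axioms deliberately retained: that is the defect
    elif defect == "dangling_ref":
        victim = rng.choice(compiled)
        out.add_axiom(SubClassOf(Named(victim),
                                 Named(Curie("UBERON", "9999999"))))
    elif defect == "accidental_equivalence":
        a, b = sorted(rng.sample(compiled, 2), key=str)
        out.add_axiom(SubClassOf(Named(a), Named(b)))
        out.add_axiom(SubClassOf(Named(b), Named(a)))
    else:
        raise OntologyError(
            f"unknown defect {defect!r}; expected one of {DEFECT_IDS}")
    return out


# Re-export the oracle here so the fixtures module is the single entry point
# for test inputs and independent verification.
from .oracle import brute_force_subsumers  # noqa: E402,F401
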