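# eqtraits

An Entity-Quality (EQ) trait-ontology toolkit for phenomics knowledge
engineering: it compiles design-pattern templates into logically defined
biological-attribute classes, classifies them with a built-in OWL 2 EL
saturation reasoner, materialises the entailed relation graph, infers links
from phenotypic-abnormality ontologies to state-neutral trait terms, aligns
external trait vocabularies lexically, and runs release quality control.

## Who this is for

Ontology engineers and phenomics data integrators who maintain trait
vocabularies of the form *"blood lysine amount"* or *"trochanter size"*.  A
trait (biological attribute) is state-neutral; a phenotype such as
*Hypolysinemia* is an abnormal state of that trait.  Keeping the two linked
by logic rather than by hand is what this toolkit automates, at desk scale
and with zero external downloads: all inputs used by the tests are generated
by the `eqtraits.fixtures` module.

## The model

Every trait class is defined with the EQ pattern in the OWL 2 EL fragment
(named classes, intersections, existential restrictions):

```
"blood lysine amount"  ≡  amount ⊓ ∃characteristic_of.(lysine ⊓ ∃part_of.blood)
"trochanter size"      ≡  size ⊓ ∃characteristic_of.trochanter
```

Classification is never asserted between trait terms; it is entailed.  Three
mechanisms carry the inferences:

* **Reference hierarchies** — lysine ⊑ amino acid in the chemical reference
  makes "blood lysine amount" ⊑ "blood amino acid amount" automatically.
* **GCI templates** — each compiled term carries a general concept inclusion
  `Q ⊓ ∃characteristic_of.(∃part_of.E) ⊑ ∃part_of.(Q ⊓ ∃characteristic_of.E)`
  which propagates anatomical part-of structure into the trait space
  ("ulna size" *part of* "forelimb skeleton size") without ever making
  "eye size" an *is_a* child of "head size".
* **Role chains** — `characteristic_of ∘ part_of ⊑ characteristic_of_part_of`
  enables queries such as *morphology of any part of the cardiovascular
  system* even when no such class exists.

Reasoning is consequence-based saturation over the subexpression closure
(init, told subsumption, conjunction decomposition/composition, existential
introduction/propagation, role hierarchy, binary role chains): sound,
complete and polynomial on this fragment.  An independently implemented
brute-force fixpoint (`eqtraits.oracle`) cross-checks the reasoner exactly
on hundreds of seeded random ontologies.

## Worked example

Write the generated fixture bundle to disk, then ask for the morphology of
anything that is part of the cardiovascular system:

```
$ eqtraits fixtures --out fix/
$ eqtraits query --input release.ofn \
    --expression "PATO:0000051 and (RO:0002314 some UBERON:0004535)"
OBA:1000005	heart morphology
OBA:1000006	aorta morphology
```

Only heart and aorta morphology are retrieved — head morphology is
correctly excluded because the head is not part of the cardiovascular
system.  Linking the mini phenotype ontology against the compiled traits:

```
$ eqtraits link --traits release.ofn --phenotypes fix/mini_phenotype.ofn \
    --out links.sssom.tsv --summary summary.json
```

produces six SSSOM rows, one per EQ-defined abnormality, e.g.

```
MP:0030719  decreased circulating lysine level  skos:broadMatch  OBA:2020005  blood lysine amount   semapv:LogicalReasoning
MP:0000252  microcephaly                        skos:broadMatch  OBA:VT0000047  head circumference  semapv:LogicalReasoning
```

Each row says the abnormal state is a manifestation (narrower match) of the
state-neutral attribute, derived purely by reasoning: microcephaly is
defined on a severely decreased head circumference, so it lands under the
"head circumference" trait (and only there — the shallower "head size"
superclass is suppressed as redundant).  The three unmapped classes in
`summary.json` are the phenotype root and the two classes that carry no EQ
definition.

The whole pipeline (compile → classify → relation-graph → link/match → QC)
runs from one config: `eqtraits run --config config.yaml`.  Exit codes are
0 (clean), 1 (QC error), 2 (input/parse error).

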