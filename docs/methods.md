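# Methods

## Scope and model

`eqtraits` implements the computational core of Entity-Quality (EQ) trait
ontology engineering: a trait ("biological attribute") is a characteristic
Q restricted to a biological entity E via an existential property,

    T(E, Q)  ≡  Q ⊓ ∃characteristic_of.E

with E itself possibly composite (a chemical located in an anatomical
entity: `lysine ⊓ ∃part_of.blood`) or role-mediated
(`∃has_role.'serum metabolite'`).  Phenotypic abnormalities reuse the same
shape with a *state* quality and an abnormality modifier,

    P  ≡  Q_state ⊓ ∃characteristic_of.E ⊓ ∃has_modifier.abnormal

so that a reasoner derives P ⊑ T(E, Q) whenever Q_state ⊑ Q.  Everything is
kept inside the OWL 2 EL fragment: named classes, intersections,
existentials, subclass axioms (GCIs allowed), one equivalence per named
class, role hierarchies and binary role chains.  Parsers reject anything
beyond this fragment explicitly rather than dropping it; this is a
deliberate, stronger choice than tolerating beyond-EL imports with
possibly-incomplete reasoning.

## Reasoner

`reasoner.classify` saturates completion rules over the subexpression
closure of the ontology plus any query expressions:

| rule | premise → conclusion |
|---|---|
| init | X ⊑ X, X ⊑ ⊤ |
| told | X ⊑ Y, (Y ⊑ Z) asserted → X ⊑ Z |
| ⊓⁻ | X ⊑ ⊓Cᵢ → X ⊑ Cᵢ |
| ⊓⁺ | X ⊑ Cᵢ ∀i, ⊓Cᵢ ∈ closure → X ⊑ ⊓Cᵢ |
| ∃-edge | X ⊑ ∃r.Y → edge r(X,Y) |
| ∃⁺ | edge r(X,Y), Y ⊑ Z, ∃r.Z ∈ closure → X ⊑ ∃r.Z |
| hierarchy | edge r(X,Y), r ⊑* s → edge s(X,Y) |
| chain | edge a(X,Y), edge b(Y,Z), a∘b ⊑ t → edge t(X,Z) |

Derived facts never leave closure × closure (asserted at the end of every
saturation), so termination is polynomial in the number of subexpressions.
Equivalences are processed as two subclass axioms.  The agenda is a FIFO
worklist seeded in sorted order; the fixpoint is order-independent, and all
writers sort their output, so artifacts are byte-deterministic.

`entails(ont, sub, sup)` adds the two canonicalized expressions to the
closure and reads the answer off the expression-level saturation map —
equivalent to the textbook fresh-query-class encoding but without mutating
the ontology.  `query_named_subclasses` excludes deprecated terms.

There is no ⊥/disjointness in the fragment, so unsatisfiability cannot
occur; the release-level "consistency" check is structural (see QC).

**Verification.** `oracle.brute_force_subsumers` is an independent naive
fixpoint over the same closure, formulated differently (a subsumption-pair
relation closed under transitivity, conjunction rules, existential
monotonicity, plus an existential-arrow relation for role chains), written
with no shared saturation code and guarded to ≤ 40 named classes.  The
acceptance suite compares both implementations exactly on 200 seeded
random ontologies with 5–25 classes, 1–3 roles and 10–60 axioms (sizes
drawn under a fixed meta-seed); a spot sample of 40 runs in the unit
suite, together with a 30-seed monotonicity property (adding axioms never
removes entailments).

## Pattern compiler

Patterns are YAML documents with ordered variables (each carrying a
semantic range class), `%s`-slot text templates for label/definition/
synonyms, an equivalence schema and optional GCI schemas written in a
Manchester-like expression syntax.  Range checking is semantic — a binding
must classify under the variable's range in the reference ontologies — not
prefix-based.  The `entity` variable of the basic entity-attribute pattern
is ranged at `owl:Thing` because biological entities span anatomy,
chemicals and processes; narrower patterns (chemical-in-entity, role)
constrain their variables to the chemical-entity and chemical-role roots.

The per-row GCI schema is

    Q ⊓ ∃characteristic_of.(∃part_of.E) ⊑ ∃part_of.(Q ⊓ ∃characteristic_of.E)

which provably yields "ulna size ⊑ ∃part_of.forelimb skeleton size" in EL
whenever `ulna ⊑ ∃part_of.'forelimb skeleton'` is asserted in the anatomy
reference and both trait terms are compiled.  Compiled fragments assert no
subclass link between two compiled terms (tested by scanning the axiom
list); the polyhierarchy (mean parents > 1 on the fixture: "head
circumference" sits under both "head size" and "circumference") is
entirely reasoner-derived.

Label word order comes solely from each pattern's name template ("%s %s"
over (entity, attribute) gives "trochanter size"; the three-slot
chemical-in-entity template gives "blood glucose amount").  The default
definition template for two-variable patterns is "The ATTRIBUTE of
ENTITY."; patterns may override it.

`derive_trait_candidates` inverts the abnormality shape: for each
phenotype equivalence it takes the nearest attribute-level ancestor of the
state quality (attribute-level is marked by an OBO subset,
`attribute_slim`, on the characteristics hierarchy — "amount" is in it,
"decreased amount" is not; "nearest" = the candidate subsumed by all other
candidates) and copies the named entity filler.  Classes with complex
entity fillers or without an equivalence are reported as skipped, not
errors.  Proposed rows carry a needs-review flag and freshly minted
sequential 7-digit identifiers; externally tagged locals (`VT…`) are never
re-minted.

## Relation graph

`materialize` emits every entailed (C, r, D) over live named classes for
the requested roles, computed by one augmented saturation with all
candidate `∃r.D` expressions added to the closure, plus is_a edges as the
transitive reduction of the inferred taxonomy.  An edge is flagged
redundant when a deeper edge plus the hierarchy implies it;
`nonredundant`/`closure` split and exactly regenerate the full set (tested
on the fixture for one- and two-role graphs).  Reflexive role edges are
suppressed by default behind a flag.  Complex existential fillers are
traversed during saturation but never surfaced as nodes.

## Linker

Merge → classify → materialise → extract: each live phenotype class
contributes one SSSOM row per nonredundant (deepest) compiled-trait
superclass, predicate `skos:broadMatch` (the abnormal state is narrower
than the neutral attribute), justification `semapv:LogicalReasoning`.
Emitting only the deepest attribute avoids flooding the output with links
to very general attributes; the full closure is available via
`emit_closure=True`, and link counts are taken from the extracted row set,
never the axiom list.  Ontologies that share no reference vocabulary
produce a warning and an empty result rather than an error.

## Matcher

Normalisation is lowercase → punctuation stripping → whitespace
tokenisation → stop-word removal.  The default stoplist is
{measurement, measurements, trait, traits}; no further normalisation steps
(stemming, word reordering) are applied, deliberately — exactness of the
match kinds matters more than recall here.  Matching tries exact forms
first (label–label, then synonym-mediated, EXACT synonyms only); an
external term whose normalised form hits two trait terms is ambiguous and
yields no match with a note, since that signals a trait-side uniqueness
problem.  Only terms carrying logical definitions are match targets, so
reference fillers copied into a release (e.g. "lysine") can never be
mistaken for traits.

Decomposition scans the normalised label for maximal contiguous token runs
equal to a reference term's normalised label or exact synonym —
longest-match, leftmost, non-overlapping, with earlier reference
ontologies in the configured order (chemicals, anatomy, characteristics)
claiming tokens first.  Fillers are assigned to pattern variables by
semantic range; the pattern assigning the most fillers with the fewest
unfilled variables wins, earlier patterns break ties.  Curator decisions
round-trip through a plain TSV review file; accepted exact matches become
`semapv:LexicalMatching` SSSOM rows and accepted decompositions become
filler rows with minted identifiers.

## QC

Five registered checks on a classified release (the release namespace is
the root term's prefix):

* ROOT_COVERAGE — every live compiled term classifies under the root
  attribute term (the root is declared equivalent to the characteristics
  root, so coverage is an entailment, not an assertion).
* UNIQUENESS — no two distinct live compiled terms are logically
  equivalent (duplicate definitions).
* CONSISTENCY — no asserted subsumption cycles among compiled terms
  (the structural stand-in for logical consistency in a ⊥-free fragment).
  Cycle-induced equivalences are reported here and suppressed from
  UNIQUENESS, so each defect class triggers exactly one check.
* OBSOLETION — deprecated terms carry the "obsolete " label prefix and no
  logical axioms; a redefinition without a replacement pointer is a
  warning.
* DANGLING_REF — axioms reference only declared identifiers.

Exit codes (library and CLI): 0 clean, 1 any ERROR-severity violation,
2 input/parse error.

## Fixtures: what they emulate, and what they do not

The bundle stands in for Uberon/ChEBI/PATO/MP extracts: ~12 anatomy terms
with part-of structure, a 7-term chemical hierarchy with roles, a 13-term
characteristics hierarchy with an attribute-level subset, 14 compiled
trait terms across three patterns, and a 9-term phenotype ontology (6
EQ-defined abnormality classes, 2 undecomposable, 1 root).  The external
vocabulary has 10 plain labels designed so 8 match exactly (several only
after stop-word removal or via a synonym), one decomposes, one matches
nothing.  These exercise every code path the production-scale workflow
uses, but passing on them shows logical and procedural correctness — not
robustness to the lexical noise, scale (tens of thousands of classes) or
beyond-EL axioms of real reference ontology releases.

Random ontologies for the oracle suite draw all existential fillers from
the declared class set, which keeps the subexpression closure (and hence
the naive oracle) bounded; axiom-kind weights favour plain subsumptions
over GCIs and role axioms, roughly mirroring the axiom mix of curated
ontologies.

## Numerical and procedural choices

* Canonical expression order: lexicographic on (variant tag, role id,
  recursive operand keys); conjunctions are flattened, deduplicated and
  sorted, so canonical-form equality is a congruence for equivalence.
* Identifier minting starts at a configured value (default 9000001),
  zero-padded to 7 digits.
* All writers sort by identifier; byte-identical reruns are a tested
  contract of the pipeline.
* Degenerate inputs: empty ontologies classify to reflexivity + ⊤; empty
  mapping sets serialise to a header-only file; an absent confidence is an
  empty SSSOM cell, never 0.

## Known limitations

* No ⊥, nominals, self-restrictions, datatypes, domain/range axioms, or
  incremental reclassification; role chains are binary only.
* OBO writing covers only the flat subset (no nested expressions); nested
  EQ definitions serialise to functional syntax.
* The matcher is exact-match only by design: no fuzzy or embedding
  similarity, no cross-lingual labels.
* The oracle is exponential-ish in practice and guarded to 40 classes; it
  is a verification device, not a reasoner.
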