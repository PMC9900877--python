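"""Phenotype-to-trait integration: merge, reason, materialise, extract.

The four-step workflow links an ontology of phenotypic abnormalities (EQ
definitions of abnormal states) to a compiled trait ontology: (1) merge the
two, (2) classify the merged ontology, (3) materialise the entailed
subsumption graph, (4) extract phenotype -> trait subsumptions as SSSOM
mapping rows.  Links are counted on the materialised graph, not the axiom
list, and by default only the deepest (nonredundant) trait superclass of
each phenotype is emitted, so that output is not flooded with links to very
general attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .io.sssom import JUSTIFICATION_LOGICAL, SSSOMRow
from .model import Curie, Named, Ontology, OntologyError
from .reasoner import ClassificationResult, classify

#: Phenotypes are narrower than the state-neutral attribute they manifest.
PHENOTYPE_TRAIT_PREDICATE = "skos:broadMatch"


@dataclass
class LinkSummary:
    links: int
    classes_under_root: int
    unmapped: list[Curie] = field(default_factory=list)


def _trait_terms(traits: Ontology) -> list[Curie]:
    """Compiled trait terms: live classes carrying an equivalence axiom."""
    from .model import EquivalentTo
    defined = {ax.named for ax in traits.axioms
               if isinstance(ax, EquivalentTo)}
    return [c for c in traits.live_terms() if c in defined]


def link_phenotypes(traits: Ontology, pheno: Ontology,
                    emit_closure: bool = False
                    ) -> tuple[list[SSSOMRow], LinkSummary]:
    """Extract phenotype -> trait mappings as SSSOM rows.

    For each live phenotype class P and each entailed trait superclass A,
    one row with justification LogicalReasoning.  With the default
    ``emit_closure=False`` only nonredundant (deepest) trait superclasses
    are emitted; the full closure is available on request.
    """
    shared = (set(map(str, traits.terms)) | set(map(str, traits.roles))) & \
             (set(map(str, pheno.terms)) | set(map(str, pheno.roles)))
    pheno_only_refs = {str(c) for ax in pheno.axioms
                       for c in _axiom_classes(ax)} - set(map(str, pheno.terms))
    if pheno_only_refs and not (pheno_only_refs & set(map(str, traits.terms))):
        warnings.warn(
            "trait and phenotype ontologies share no reference vocabulary; "
            "no links can be inferred")
        return [], LinkSummary(links=0, classes_under_root=0,
                               unmapped=sorted(pheno.live_terms(), key=str))

    merged = traits.merge(pheno)
    result = classify(merged)
    trait_terms = [c for c in _trait_terms(traits)]
    trait_set = set(trait_terms)
    pheno_classes = pheno.live_terms()

    rows: list[SSSOMRow] = []
    unmapped: list[Curie] = []
    n_under = 0
    for p in pheno_classes:
        if p in trait_set:
            continue
        supers = [a for a in result.subsumers.get(p, set())
                  if a in trait_set and a != p
                  and not result.is_subsumed(a, p)]
        if not supers:
            unmapped.append(p)
            continue
        n_under += 1
        if emit_closure:
            chosen = supers
        else:
            chosen = [a for a in supers
                      if not any(result.strictly_subsumed(b, a)
                                 for b in supers)]
        for a in sorted(chosen, key=str):
            rows.append(SSSOMRow(
                subject_id=p, subject_label=merged.label_of(p),
                predicate_id=PHENOTYPE_TRAIT_PREDICATE,
                object_id=a, object_label=merged.label_of(a),
                mapping_justification=JUSTIFICATION_LOGICAL))
    rows.sort(key=lambda r: (str(r.subject_id), str(r.object_id)))
    summary = LinkSummary(links=len(rows), classes_under_root=n_under,
                          unmapped=sorted(unmapped, key=str))
    return rows, summary


def _axiom_classes(ax) -> set[Curie]:
    from .model import axiom_signature
    classes, _ = axiom_signature(ax)
    return classes


def manifestations(merged: Ontology, attribute: Curie,
                   phenotype_prefix: str = "MP",
                   result: Optional[ClassificationResult] = None
                   ) -> set[Curie]:
    """All phenotype-namespace classes subsumed by the given attribute in
    an already merged trait+phenotype ontology."""
    if attribute not in merged.terms:
        raise OntologyError(f"unknown attribute {attribute}")
    if result is None:
        result = classify(merged)
    out: set[Curie] = set()
    for cid in merged.live_terms():
        if cid.prefix != phenotype_prefix or cid == attribute:
            continue
        if result.is_subsumed(cid, attribute):
            out.add(cid)
    return out
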