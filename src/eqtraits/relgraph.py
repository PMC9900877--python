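"""Relation-graph materialisation: entailed named-class-to-named-class edges.

Converts a classified ontology into a knowledge graph.  For each requested
role r, every entailed ``C ⊑ r some D`` over live named classes becomes an
edge; ``is_a`` edges are the transitive reduction of the inferred taxonomy.
Edges implied by a deeper edge plus the hierarchy are flagged redundant, and
:func:`nonredundant`/:func:`closure` split and regenerate the full set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .model import Curie, Named, Ontology, OntologyError, Some
from .reasoner import ClassificationResult, classify

#: Predicate used for subsumption edges.
IS_A = Curie("rdfs", "subClassOf")


@dataclass(frozen=True, order=True)
class RelationEdge:
    subject: Curie
    predicate: Curie
    object: Curie
    redundant: bool = False

    def __str__(self) -> str:
        return f"{self.subject} -[{self.predicate}]-> {self.object}"


def materialize(ont: Ontology, result: Optional[ClassificationResult],
                roles: Iterable[Curie],
                include_reflexive: bool = False) -> set[RelationEdge]:
    """Materialise all entailed role edges plus reduced is_a edges.

    ``result`` may be passed to reuse an existing classification for the
    taxonomy part; the existential edges always require an augmented
    saturation and are recomputed here.  Reflexive role edges (C, r, C) are
    suppressed unless ``include_reflexive`` is set.
    """
    roles = sorted(set(roles), key=str)
    for r in roles:
        if r not in ont.roles:
            raise OntologyError(f"role {r} is not declared in the ontology")
    live = ont.live_terms()
    extras = [Some(r, Named(d)) for r in roles for d in live]
    augmented = classify(ont, extra_expressions=extras)
    if result is None:
        result = augmented

    edges: set[RelationEdge] = set()
    role_triples: dict[Curie, set[tuple[Curie, Curie]]] = {r: set()
                                                           for r in roles}
    for c in live:
        derived = augmented.expr_subsumers[Named(c)]
        for r in roles:
            for d in live:
                if c == d and not include_reflexive:
                    continue
                if Some(r, Named(d)) in derived:
                    role_triples[r].add((c, d))

    for r in roles:
        triples = role_triples[r]
        for (c, d) in triples:
            redundant = any(
                (c, d2) in triples and result.strictly_subsumed(d2, d)
                for d2 in live) or any(
                (c2, d) in triples and result.strictly_subsumed(c, c2)
                for c2 in live)
            edges.add(RelationEdge(c, r, d, redundant=redundant))

    live_set = set(live)
    for c in live:
        for parent in result.direct_parents.get(c, ()):
            if parent in live_set and parent != c:
                edges.add(RelationEdge(c, IS_A, parent, redundant=False))
    return edges


def nonredundant(edges: set[RelationEdge],
                 result: ClassificationResult) -> set[RelationEdge]:
    """Keep only edges not implied by another edge plus the hierarchy.

    An edge (C, r, D) is dropped when some (C, r, D') with D' strictly below
    D exists, or some (C', r, D) with C strictly below C' exists; the
    surviving minimal set regenerates the input under :func:`closure`.
    """
    by_role: dict[Curie, set[tuple[Curie, Curie]]] = {}
    for e in edges:
        by_role.setdefault(e.predicate, set()).add((e.subject, e.object))
    out: set[RelationEdge] = set()
    for e in edges:
        if e.predicate == IS_A:
            out.add(replace(e, redundant=False))
            continue
        triples = by_role[e.predicate]
        dominated = any(
            (e.subject, d2) in triples
            and result.strictly_subsumed(d2, e.object)
            for (s, d2) in triples if s == e.subject) or any(
            (c2, e.object) in triples
            and result.strictly_subsumed(e.subject, c2)
            for (c2, o) in triples if o == e.object)
        if not dominated:
            out.add(replace(e, redundant=False))
    return out


def closure(edges: set[RelationEdge], result: ClassificationResult,
            live: Iterable[Curie]) -> set[RelationEdge]:
    """Regenerate the full entailed edge set from a nonredundant core by
    pushing subjects down and objects up the subsumption hierarchy."""
    live = sorted(set(live), key=str)
    out: set[RelationEdge] = set()
    for e in edges:
        if e.predicate == IS_A:
            out.add(replace(e, redundant=False))
            continue
        for c in live:
            if not result.is_subsumed(c, e.subject):
                continue
            for d in live:
                if c == d:
                    continue
                if result.is_subsumed(e.object, d):
                    redundant = not (c == e.subject and d == e.object)
                    out.add(RelationEdge(c, e.predicate, d,
                                         redundant=redundant))
    # recompute redundancy flags consistently with materialize()
    by_role: dict[Curie, set[tuple[Curie, Curie]]] = {}
    for e in out:
        by_role.setdefault(e.predicate, set()).add((e.subject, e.object))
    final: set[RelationEdge] = set()
    for e in out:
        if e.predicate == IS_A:
            final.add(e)
            continue
        triples = by_role[e.predicate]
        redundant = any(
            (e.subject, d2) in triples
            and result.strictly_subsumed(d2, e.object)
            for (s, d2) in triples if s == e.subject) or any(
            (c2, e.object) in triples
            and result.strictly_subsumed(e.subject, c2)
            for (c2, o) in triples if o == e.object)
        final.add(RelationEdge(e.subject, e.predicate, e.object,
                               redundant=redundant))
    return final


def write_edges_tsv(edges: set[RelationEdge]) -> str:
    """Serialise edges as a deterministic TSV
    (subject, predicate, object, redundant)."""
    lines = ["subject\tpredicate\tobject\tredundant"]
    for e in sorted(edges):
        lines.append(f"{e.subject}\t{e.predicate}\t{e.object}\t"
                     f"{'true' if e.redundant else 'false'}")
    return "\n".join(lines) + "\n"
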