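"""Consequence-based saturation reasoning for the supported EL fragment.

Classification is computed by exhaustively applying completion rules over
the subexpression closure of the ontology (plus any query expressions).  The
rule set follows the standard consequence-based treatment of EL with GCIs,
role hierarchies and binary role chains:

* init:        X ⊑ X and X ⊑ ⊤ for every closure member X
* told:        X ⊑ Y and (Y ⊑ Z) asserted  ⇒  X ⊑ Z
* ⊓-decompose: X ⊑ (C1 ⊓ … ⊓ Ck)  ⇒  X ⊑ Ci
* ⊓-compose:   X ⊑ Ci for all i, (C1 ⊓ … ⊓ Ck) in closure  ⇒  X ⊑ ⊓Ci
* ∃-edge:      X ⊑ (r some Y)  ⇒  edge r(X, Y)
* ∃-compose:   edge r(X, Y), Y ⊑ Z, (r some Z) in closure  ⇒  X ⊑ (r some Z)
* hierarchy:   edge r(X, Y), r ⊑* s  ⇒  edge s(X, Y)
* chain:       edge a(X, Y), edge b(Y, Z), a∘b ⊑ t  ⇒  edge t(X, Z)

Every derived fact stays inside closure × closure, so saturation terminates
in polynomial time in the number of subexpressions.  The algorithm is sound
and complete for subsumptions between closure members, which is all that
classification and query answering need; an independently implemented
brute-force fixpoint (see :mod:`eqtraits.oracle`) serves as the test oracle.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import (And, Axiom, ClassExpression, Curie, EquivalentTo, Named,
                    Ontology, OntologyError, RoleChain, Some, SubClassOf,
                    SubRoleOf, TOP, canonicalize, subexpressions)


class ReasonerError(OntologyError):
    pass


def role_superroles(ont: Ontology) -> dict[Curie, set[Curie]]:
    """Reflexive-transitive closure of the told role hierarchy."""
    roles: set[Curie] = set(ont.roles)
    subs: list[tuple[Curie, Curie]] = []
    for ax in ont.axioms:
        if isinstance(ax, SubRoleOf):
            roles.update((ax.sub, ax.sup))
            subs.append((ax.sub, ax.sup))
        elif isinstance(ax, RoleChain):
            roles.update((ax.first, ax.second, ax.sup))
    closure = {r: {r} for r in roles}
    changed = True
    while changed:
        changed = False
        for sub, sup in subs:
            for s in list(closure[sup]):
                if s not in closure[sub]:
                    closure[sub].add(s)
                    changed = True
    return closure


@dataclass
class ClassificationResult:
    """Subsumption preorder over named classes with equivalence partition.

    ``subsumers[C]`` is the exact set of named classes D (plus ``owl:Thing``)
    with ``ont ⊨ C ⊑ D``; ``direct_parents`` is the transitive reduction of
    the induced partial order on equivalence classes.
    """

    subsumers: dict[Curie, set[Curie]]
    equivalence_classes: list[frozenset[Curie]]
    direct_parents: dict[Curie, set[Curie]]
    #: full saturation map canonical expr -> set of canonical subsumer exprs
    expr_subsumers: dict[ClassExpression, set[ClassExpression]] = field(
        default_factory=dict, repr=False)

    def is_subsumed(self, sub: Curie, sup: Curie) -> bool:
        return sup in self.subsumers.get(sub, set())

    def strictly_subsumed(self, sub: Curie, sup: Curie) -> bool:
        return self.is_subsumed(sub, sup) and not self.is_subsumed(sup, sub)

    def equivalents(self, cid: Curie) -> frozenset[Curie]:
        for group in self.equivalence_classes:
            if cid in group:
                return group
        return frozenset({cid})


def _closure_of(ont: Ontology,
                extra: Iterable[ClassExpression]) -> list[ClassExpression]:
    closure: set[ClassExpression] = {TOP}
    for cid in ont.terms:
        closure.add(Named(cid))
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            exprs = (ax.sub, ax.sup)
        elif isinstance(ax, EquivalentTo):
            exprs = (Named(ax.named), ax.expr)
        else:
            continue
        for expr in exprs:
            for sub in subexpressions(canonicalize(expr)):
                closure.add(sub)
    for expr in extra:
        for sub in subexpressions(canonicalize(expr)):
            closure.add(sub)
    from .model import expr_key
    return sorted(closure, key=expr_key)


def _saturate(ont: Ontology, extra: Iterable[ClassExpression] = ()
              ) -> tuple[dict[ClassExpression, set[ClassExpression]],
                         dict[Curie, dict[ClassExpression, set[ClassExpression]]]]:
    """Run the completion rules; return (S, out-edges per role)."""
    closure = _closure_of(ont, extra)
    closure_set = set(closure)

    told: dict[ClassExpression, list[ClassExpression]] = {}
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            pairs = [(canonicalize(ax.sub), canonicalize(ax.sup))]
        elif isinstance(ax, EquivalentTo):
            named = Named(ax.named)
            expr = canonicalize(ax.expr)
            pairs = [(named, expr), (expr, named)]
        else:
            continue
        for lhs, rhs in pairs:
            told.setdefault(lhs, []).append(rhs)

    superroles = role_superroles(ont)
    chains = [ax for ax in ont.axioms if isinstance(ax, RoleChain)]
    chains_by_first: dict[Curie, list[RoleChain]] = {}
    chains_by_second: dict[Curie, list[RoleChain]] = {}
    for ch in chains:
        chains_by_first.setdefault(ch.first, []).append(ch)
        chains_by_second.setdefault(ch.second, []).append(ch)

    # indexes over the closure
    conj_index: dict[ClassExpression, list[And]] = {}
    some_fillers: dict[Curie, set[ClassExpression]] = {}
    for expr in closure:
        if isinstance(expr, And):
            for op in expr.operands:
                conj_index.setdefault(op, []).append(expr)
        elif isinstance(expr, Some):
            some_fillers.setdefault(expr.role, set()).add(expr.filler)

    S: dict[ClassExpression, set[ClassExpression]] = {x: set() for x in closure}
    out_edges: dict[Curie, dict[ClassExpression, set[ClassExpression]]] = {}
    in_edges: dict[Curie, dict[ClassExpression, set[ClassExpression]]] = {}

    work: deque = deque()

    def add_sub(x: ClassExpression, y: ClassExpression) -> None:
        if y not in S[x]:
            S[x].add(y)
            work.append(("sub", x, y))

    def add_edge(role: Curie, x: ClassExpression, y: ClassExpression) -> None:
        for s in superroles.get(role, {role}):
            targets = out_edges.setdefault(s, {}).setdefault(x, set())
            if y not in targets:
                targets.add(y)
                in_edges.setdefault(s, {}).setdefault(y, set()).add(x)
                work.append(("edge", s, x, y))

    for x in closure:
        add_sub(x, x)
        add_sub(x, TOP)

    while work:
        fact = work.popleft()
        if fact[0] == "sub":
            _, x, y = fact
            for z in told.get(y, ()):
                add_sub(x, z)
            if isinstance(y, And):
                for op in y.operands:
                    add_sub(x, op)
            for conj in conj_index.get(y, ()):
                if all(op in S[x] for op in conj.operands):
                    add_sub(x, conj)
            if isinstance(y, Some):
                add_edge(y.role, x, y.filler)
            # x plays the filler role of rule ∃-compose: edges into x
            for role, index in in_edges.items():
                if x in index and y in some_fillers.get(role, ()):
                    target = Some(role, y)
                    for w in list(index[x]):
                        add_sub(w, target)
        else:
            _, role, x, y = fact
            for z in list(S[y]):
                if z in some_fillers.get(role, ()):
                    add_sub(x, Some(role, z))
            for ch in chains_by_first.get(role, ()):
                for z in list(out_edges.get(ch.second, {}).get(y, ())):
                    add_edge(ch.sup, x, z)
            for ch in chains_by_second.get(role, ()):
                for w in list(in_edges.get(ch.first, {}).get(x, ())):
                    add_edge(ch.sup, w, y)

    # termination sanity: nothing outside the closure was created
    assert all(y in closure_set for ys in S.values() for y in ys)
    return S, out_edges


def _partition_and_parents(subsumers: dict[Curie, set[Curie]]
                           ) -> tuple[list[frozenset[Curie]],
                                      dict[Curie, set[Curie]]]:
    named = sorted(subsumers, key=str)
    named_set = set(named)
    rep_of: dict[Curie, Curie] = {}
    groups: dict[Curie, frozenset[Curie]] = {}
    for c in named:
        group = frozenset(
            d for d in subsumers[c] & named_set if c in subsumers[d])
        rep = min(group, key=str)
        rep_of[c] = rep
        groups[rep] = group
    dag = nx.DiGraph()
    dag.add_nodes_from(groups)
    for c in named:
        for d in subsumers[c]:
            if d in named_set and rep_of[d] != rep_of[c]:
                dag.add_edge(rep_of[c], rep_of[d])
    reduced = nx.transitive_reduction(dag)
    direct: dict[Curie, set[Curie]] = {}
    for c in named:
        parents = set()
        for rep in reduced.successors(rep_of[c]):
            parents.update(groups[rep])
        direct[c] = parents
    equivalence = sorted({g for g in groups.values()},
                         key=lambda g: str(min(g, key=str)))
    return equivalence, direct


def classify(ont: Ontology,
             extra_expressions: Iterable[ClassExpression] = ()
             ) -> ClassificationResult:
    """Sound and complete classification of all named classes.

    ``extra_expressions`` are added to the saturation closure so that
    subsumption against complex query expressions can be read off the
    result; they do not change the ontology's entailments.
    """
    S, _ = _saturate(ont, extra_expressions)
    subsumers: dict[Curie, set[Curie]] = {}
    for cid in ont.terms:
        derived = S[Named(cid)]
        subsumers[cid] = {e.id for e in derived if isinstance(e, Named)
                          and (e.id in ont.terms or e == TOP)}
        subsumers[cid].add(TOP.id)
    equivalence, direct = _partition_and_parents(subsumers)
    return ClassificationResult(
        subsumers=subsumers,
        equivalence_classes=equivalence,
        direct_parents=direct,
        expr_subsumers=S,
    )


def entails(ont: Ontology, sub: ClassExpression, sup: ClassExpression) -> bool:
    """Decide ``ont ⊨ sub ⊑ sup`` by classifying with both expressions
    introduced as query members of the closure."""
    sub_c, sup_c = canonicalize(sub), canonicalize(sup)
    result = classify(ont, extra_expressions=(sub_c, sup_c))
    return sup_c in result.expr_subsumers[sub_c]


def query_named_subclasses(ont: Ontology, query: ClassExpression,
                           result: Optional[ClassificationResult] = None
                           ) -> set[Curie]:
    """All live named classes C with ``ont ⊨ C ⊑ query`` (the DL-query
    operation; deprecated terms are excluded)."""
    query_c = canonicalize(query)
    if result is None or query_c not in result.expr_subsumers:
        result = classify(ont, extra_expressions=(query_c,))
    out: set[Curie] = set()
    for cid in ont.live_terms():
        if query_c in result.expr_subsumers[Named(cid)]:
            out.add(cid)
    return out
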