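"""Brute-force subsumption oracle, independent of :mod:`eqtraits.reasoner`.

Computes entailed subsumption between all members of the subexpression
closure by naive re-scanning of semantic rewrite rules until fixpoint, with
no worklist and no rule indexing.  The formulation is different from the
consequence-based saturation in the main reasoner: it maintains a plain
subsumption relation ``rel ⊆ closure × closure`` plus derived existential
arrows, and closes them under transitivity, conjunction introduction and
elimination, existential monotonicity, role hierarchy and role chains.

This is intentionally slow and simple; it exists solely as a test oracle
for small inputs (guarded at 40 named classes).
"""

from __future__ import annotations

from .model import (And, ClassExpression, Curie, EquivalentTo, Named,
                    Ontology, OntologyError, RoleChain, Some, SubClassOf,
                    SubRoleOf, TOP, canonicalize, expr_key)

MAX_ORACLE_CLASSES = 40


def _collect_closure(ont: Ontology) -> list[ClassExpression]:
    found: set[ClassExpression] = {TOP}

    def walk(expr: ClassExpression) -> None:
        found.add(expr)
        if isinstance(expr, And):
            for op in expr.operands:
                walk(op)
        elif isinstance(expr, Some):
            walk(expr.filler)

    for cid in ont.terms:
        found.add(Named(cid))
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            walk(canonicalize(ax.sub))
            walk(canonicalize(ax.sup))
        elif isinstance(ax, EquivalentTo):
            walk(Named(ax.named))
            walk(canonicalize(ax.expr))
    return sorted(found, key=expr_key)


def _superrole_closure(ont: Ontology) -> dict[Curie, set[Curie]]:
    roles: set[Curie] = set(ont.roles)
    pairs = []
    for ax in ont.axioms:
        if isinstance(ax, SubRoleOf):
            roles.update((ax.sub, ax.sup))
            pairs.append((ax.sub, ax.sup))
        elif isinstance(ax, RoleChain):
            roles.update((ax.first, ax.second, ax.sup))
        elif isinstance(ax, (SubClassOf, EquivalentTo)):
            exprs = ((ax.sub, ax.sup) if isinstance(ax, SubClassOf)
                     else (ax.expr,))
            stack = list(exprs)
            while stack:
                e = stack.pop()
                if isinstance(e, Some):
                    roles.add(e.role)
                    stack.append(e.filler)
                elif isinstance(e, And):
                    stack.extend(e.operands)
    closure = {r: {r} for r in roles}
    changed = True
    while changed:
        changed = False
        for sub, sup in pairs:
            for s in list(closure[sup]):
                if s not in closure[sub]:
                    closure[sub].add(s)
                    changed = True
    return closure


def brute_force_entailed_pairs(ont: Ontology
                               ) -> dict[ClassExpression, set[ClassExpression]]:
    """Exact entailed subsumption over the subexpression closure."""
    closure = _collect_closure(ont)
    superroles = _superrole_closure(ont)
    chains = [(ax.first, ax.second, ax.sup) for ax in ont.axioms
              if isinstance(ax, RoleChain)]

    rel: dict[ClassExpression, set[ClassExpression]] = {
        x: {x, TOP} for x in closure}
    arrows: dict[Curie, set[tuple[ClassExpression, ClassExpression]]] = {
        r: set() for rs in superroles.values() for r in rs}
    for r in superroles:
        arrows.setdefault(r, set())

    # base facts: told axioms and conjunction elimination
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            rel[canonicalize(ax.sub)].add(canonicalize(ax.sup))
        elif isinstance(ax, EquivalentTo):
            named, expr = Named(ax.named), canonicalize(ax.expr)
            rel[named].add(expr)
            rel[expr].add(named)
    for x in closure:
        if isinstance(x, And):
            for op in x.operands:
                rel[x].add(op)

    conjunctions = [x for x in closure if isinstance(x, And)]
    existentials = [x for x in closure if isinstance(x, Some)]

    changed = True
    while changed:
        changed = False
        # transitivity
        for x in closure:
            gained: set[ClassExpression] = set()
            for y in rel[x]:
                gained |= rel[y]
            if not gained <= rel[x]:
                rel[x] |= gained
                changed = True
        # conjunction introduction
        for conj in conjunctions:
            ops = set(conj.operands)
            for x in closure:
                if conj not in rel[x] and ops <= rel[x]:
                    rel[x].add(conj)
                    changed = True
        # existential monotonicity (incl. role hierarchy)
        for some in existentials:
            for target in existentials:
                if target in rel[some]:
                    continue
                if (target.role in superroles.get(some.role, {some.role})
                        and target.filler in rel[some.filler]):
                    rel[some].add(target)
                    changed = True
        # arrows from subsumption by an existential
        for x in closure:
            for y in rel[x]:
                if isinstance(y, Some):
                    for s in superroles.get(y.role, {y.role}):
                        if (x, y.filler) not in arrows[s]:
                            arrows[s].add((x, y.filler))
                            changed = True
        # role chains
        for first, second, sup in chains:
            for (x, y) in list(arrows.get(first, ())):
                for (y2, z) in list(arrows.get(second, ())):
                    if y2 == y:
                        for s in superroles.get(sup, {sup}):
                            if (x, z) not in arrows[s]:
                                arrows[s].add((x, z))
                                changed = True
        # arrows back into subsumption against closure existentials
        for some in existentials:
            for (x, z) in list(arrows.get(some.role, ())):
                if some not in rel[x] and some.filler in rel[z]:
                    rel[x].add(some)
                    changed = True
    return rel


def brute_force_subsumers(ont: Ontology):
    """Oracle counterpart of :func:`eqtraits.reasoner.classify`.

    Returns a :class:`~eqtraits.reasoner.ClassificationResult` whose
    subsumer sets are computed by the naive fixpoint above.  Guarded to
    small inputs.
    """
    from .reasoner import ClassificationResult, _partition_and_parents

    if len(ont.terms) > MAX_ORACLE_CLASSES:
        raise OntologyError(
            f"oracle guard: {len(ont.terms)} named classes exceeds "
            f"{MAX_ORACLE_CLASSES}")
    rel = brute_force_entailed_pairs(ont)
    subsumers: dict[Curie, set[Curie]] = {}
    for cid in ont.terms:
        subsumers[cid] = {e.id for e in rel[Named(cid)]
                          if isinstance(e, Named)
                          and (e.id in ont.terms or e == TOP)}
        subsumers[cid].add(TOP.id)
    equivalence, direct = _partition_and_parents(subsumers)
    return ClassificationResult(subsumers=subsumers,
                                equivalence_classes=equivalence,
                                direct_parents=direct,
                                expr_subsumers=rel)
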