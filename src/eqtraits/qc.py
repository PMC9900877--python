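"""Release quality-control checks.

The registry covers the checks run on every change to a compiled trait
release: every live compiled term must classify under the root attribute
term (ROOT_COVERAGE); no two live compiled terms may be logically
equivalent (UNIQUENESS — duplicated definitions); asserted subsumption
cycles among compiled terms are structural inconsistencies (CONSISTENCY);
deprecated terms must follow the obsoletion convention — "obsolete " label
prefix, no logical axioms, ideally a replacement pointer (OBSOLETION); and
axioms must not reference undeclared identifiers (DANGLING_REF).

The supported EL fragment has no negation or disjointness, so
unsatisfiability cannot arise; "logically consistent" is therefore
operationalised structurally as the absence of unintended equivalences
(asserted subsumption cycles) between distinct compiled terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import (Curie, EquivalentTo, Named, OBSOLETE_PREFIX, Ontology,
                    OntologyError, SubClassOf)
from .reasoner import ClassificationResult, classify

CHECK_IDS = ("ROOT_COVERAGE", "UNIQUENESS", "CONSISTENCY", "OBSOLETION",
             "DANGLING_REF")


@dataclass
class QCViolation:
    check_id: str
    severity: str  # ERROR | WARNING
    subjects: list[Curie]
    message: str

    def __post_init__(self):
        if self.check_id not in CHECK_IDS:
            raise OntologyError(f"unknown check id {self.check_id!r}")
        if not self.subjects:
            raise OntologyError("violation without subjects")


def _compiled_terms(ont: Ontology, root: Curie) -> list[Curie]:
    """Terms in the release namespace (same prefix as the root), excluding
    the root itself and deprecated terms."""
    return [c for c in ont.live_terms()
            if c.prefix == root.prefix and c != root]


def run_qc(ont: Ontology, result: Optional[ClassificationResult],
           root: Curie) -> list[QCViolation]:
    """Run all registered checks on a classified release; return the
    violations (empty list for a clean release)."""
    if root not in ont.terms:
        raise OntologyError(f"unknown root term {root}")
    if result is None:
        result = classify(ont)
    violations: list[QCViolation] = []
    compiled = _compiled_terms(ont, root)
    compiled_set = set(compiled)

    # ROOT_COVERAGE: every live compiled term classifies under the root
    for c in compiled:
        if not result.is_subsumed(c, root):
            violations.append(QCViolation(
                "ROOT_COVERAGE", "ERROR", [c],
                f"{c} ({ont.label_of(c)}) is not subsumed by the root "
                f"attribute term {root}"))

    # CONSISTENCY: asserted subsumption cycles among compiled terms
    told = nx.DiGraph()
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) \
                and isinstance(ax.sup, Named):
            if ax.sub.id in compiled_set and ax.sup.id in compiled_set:
                told.add_edge(ax.sub.id, ax.sup.id)
    cyclic_pairs: set[frozenset[Curie]] = set()
    for scc in nx.strongly_connected_components(told):
        if len(scc) > 1:
            members = sorted(scc, key=str)
            cyclic_pairs.update(
                frozenset((a, b)) for i, a in enumerate(members)
                for b in members[i + 1:])
            violations.append(QCViolation(
                "CONSISTENCY", "ERROR", members,
                "asserted subsumption cycle merges distinct attribute "
                "terms: " + ", ".join(map(str, members))))

    # UNIQUENESS: distinct live compiled terms that are logically
    # equivalent (duplicate definitions); cycles are reported above
    for group in result.equivalence_classes:
        dupes = sorted(group & compiled_set, key=str)
        if len(dupes) > 1:
            all_cyclic = all(
                frozenset((a, b)) in cyclic_pairs
                for i, a in enumerate(dupes) for b in dupes[i + 1:])
            if not all_cyclic:
                violations.append(QCViolation(
                    "UNIQUENESS", "ERROR", dupes,
                    "equivalent attribute terms (no other equivalent "
                    "attribute may exist): "
                    + ", ".join(f"{d} ({ont.label_of(d)})" for d in dupes)))

    # OBSOLETION: deprecated terms follow the obsoletion convention
    for cid, rec in sorted(ont.terms.items(), key=lambda kv: str(kv[0])):
        if not rec.deprecated:
            continue
        if not rec.label.startswith(OBSOLETE_PREFIX):
            violations.append(QCViolation(
                "OBSOLETION", "ERROR", [cid],
                f"deprecated term {cid} label does not start with "
                f"{OBSOLETE_PREFIX!r}"))
        retained = [ax for ax in ont.axioms
                    if (isinstance(ax, EquivalentTo) and ax.named == cid)
                    or (isinstance(ax, SubClassOf)
                        and isinstance(ax.sub, Named) and ax.sub.id == cid)]
        if retained:
            violations.append(QCViolation(
                "OBSOLETION", "ERROR", [cid],
                f"deprecated term {cid} retains {len(retained)} logical "
                "axiom(s); obsoletion removes all logical axioms"))
        if rec.replaced_by is None and retained:
            violations.append(QCViolation(
                "OBSOLETION", "WARNING", [cid],
                f"deprecated term {cid} was redefined without a "
                "replacement pointer"))

    # DANGLING_REF: axioms referencing undeclared identifiers
    missing = ont.undeclared_references()
    if missing:
        violations.append(QCViolation(
            "DANGLING_REF", "ERROR", missing,
            "axioms reference undeclared identifiers: "
            + ", ".join(map(str, missing))))

    return violations


def has_errors(violations: list[QCViolation]) -> bool:
    return any(v.severity == "ERROR" for v in violations)


def violations_as_dicts(violations: list[QCViolation]) -> list[dict]:
    return [{"check_id": v.check_id, "severity": v.severity,
             "subjects": [str(s) for s in v.subjects],
             "message": v.message} for v in violations]
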