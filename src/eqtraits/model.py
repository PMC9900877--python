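"""Core data model: CURIEs, EL class expressions, axioms, term records, ontologies.

The representable logic is deliberately restricted to the OWL 2 EL fragment
used by Entity-Quality trait modelling: named classes, intersections and
existential restrictions, plus subclass axioms (including general concept
inclusions with a complex left-hand side), equivalences between a named class
and an expression, role hierarchies and binary role chains.  Anything beyond
that fragment is rejected at parse time with an explicit error rather than
silently dropped.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union


class OntologyError(Exception):
    """Base class for all errors raised by this package."""


class CurieError(OntologyError):
    """Raised when an identifier cannot be parsed against the prefix map."""


class UnsupportedConstructError(OntologyError):
    """Raised when input uses logic outside the supported EL fragment."""


# --------------------------------------------------------------------------
# Identifiers
# --------------------------------------------------------------------------

#: OBO PURL base shared by all OBO Foundry ontologies.
OBO_BASE = "http://purl.obolibrary.org/obo/"

#: Prefixes that expand to OBO-style PURLs (``<base><PREFIX>_<local>``).
_OBO_PREFIXES = (
    "OBA", "UBERON", "CHEBI", "PATO", "RO", "BFO", "MP", "HP", "GO",
    "CL", "PR", "SO", "NBO", "MONDO", "VT", "IAO", "TST",
)

#: Non-OBO namespaces used for annotations and mapping predicates.
_STANDARD_PREFIXES = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "oboInOwl": "http://www.geneontology.org/formats/oboInOwl#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "semapv": "https://w3id.org/semapv/vocab/",
    "EFO": "http://www.ebi.ac.uk/efo/EFO_",
}


def default_prefixes() -> dict[str, str]:
    """Return the default prefix map (OBO PURL conventions plus annotation
    namespaces).  Callers may copy and extend it."""
    prefixes = {p: f"{OBO_BASE}{p}_" for p in _OBO_PREFIXES}
    prefixes.update(_STANDARD_PREFIXES)
    return prefixes


@dataclass(frozen=True, order=True)
class Curie:
    """A compact identifier ``prefix:local``.

    ``local`` is usually numeric but may carry a literal source tag (for
    example ``VT0000188`` for terms derived from an external vocabulary);
    tagged locals are preserved verbatim and never re-minted.  Comparison is
    case-sensitive on both fields.
    """

    prefix: str
    local: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"

    def expand(self, prefixes: Optional[dict[str, str]] = None) -> str:
        """Expand to the canonical PURL/IRI form."""
        prefixes = prefixes if prefixes is not None else default_prefixes()
        try:
            base = prefixes[self.prefix]
        except KeyError:
            raise CurieError(f"unknown prefix {self.prefix!r} in {self}") from None
        return f"{base}{self.local}"


def parse_curie(text: str, prefixes: Optional[dict[str, str]] = None) -> Curie:
    """Parse a CURIE (``PFX:local``) or a full PURL into a :class:`Curie`.

    PURLs are matched against the declared prefix bases, longest base first,
    so that ``http://purl.obolibrary.org/obo/OBA_2020005`` round-trips to
    ``OBA:2020005``.  Unknown prefixes raise :class:`CurieError` naming the
    offending token.
    """
    prefixes = prefixes if prefixes is not None else default_prefixes()
    if text.startswith(("http://", "https://")):
        for prefix, base in sorted(prefixes.items(), key=lambda kv: -len(kv[1])):
            if text.startswith(base) and len(text) > len(base):
                return Curie(prefix, text[len(base):])
        raise CurieError(f"IRI {text!r} matches no declared prefix base")
    if ":" not in text:
        raise CurieError(f"not a CURIE or IRI: {text!r}")
    prefix, local = text.split(":", 1)
    if prefix not in prefixes:
        raise CurieError(f"unknown prefix {prefix!r} in {text!r}")
    if not local:
        raise CurieError(f"empty local part in {text!r}")
    return Curie(prefix, local)


# --------------------------------------------------------------------------
# Class expressions (EL fragment)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Named:
    """A named class."""

    id: Curie


@dataclass(frozen=True)
class And:
    """An intersection of two or more class expressions."""

    operands: tuple["ClassExpression", ...]


@dataclass(frozen=True)
class Some:
    """An existential restriction ``role some filler``."""

    role: Curie
    filler: "ClassExpression"


ClassExpression = Union[Named, And, Some]

#: owl:Thing; implicit superclass of everything.
TOP = Named(Curie("owl", "Thing"))


def expr_key(expr: ClassExpression):
    """Total order key over class expressions: (variant tag, role id,
    recursive operand keys).  Used for canonical sorting and hashing."""
    if isinstance(expr, Named):
        return (0, str(expr.id))
    if isinstance(expr, Some):
        return (1, str(expr.role), expr_key(expr.filler))
    return (2, tuple(expr_key(op) for op in expr.operands))


def canonicalize(expr: ClassExpression) -> ClassExpression:
    """Return the canonical form: nested intersections flattened, operands
    deduplicated and sorted, singleton intersections collapsed.

    Idempotent, and a congruence for entailment: two expressions with equal
    canonical forms are logically equivalent.
    """
    if isinstance(expr, Named):
        return expr
    if isinstance(expr, Some):
        return Some(expr.role, canonicalize(expr.filler))
    flat: list[ClassExpression] = []
    for op in expr.operands:
        c = canonicalize(op)
        if isinstance(c, And):
            flat.extend(c.operands)
        else:
            flat.append(c)
    unique = sorted(set(flat), key=expr_key)
    if len(unique) == 1:
        return unique[0]
    return And(tuple(unique))


def subexpressions(expr: ClassExpression) -> Iterator[ClassExpression]:
    """Yield ``expr`` and all of its subexpressions (pre-order)."""
    yield expr
    if isinstance(expr, And):
        for op in expr.operands:
            yield from subexpressions(op)
    elif isinstance(expr, Some):
        yield from subexpressions(expr.filler)


def expr_signature(expr: ClassExpression) -> set[Curie]:
    """All class and role identifiers occurring in the expression."""
    out: set[Curie] = set()
    for sub in subexpressions(expr):
        if isinstance(sub, Named):
            out.add(sub.id)
        elif isinstance(sub, Some):
            out.add(sub.role)
    return out


# --------------------------------------------------------------------------
# Axioms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SubClassOf:
    """``sub SubClassOf sup``; a complex ``sub`` makes this a GCI."""

    sub: ClassExpression
    sup: ClassExpression


@dataclass(frozen=True)
class EquivalentTo:
    """``named EquivalentTo expr``; the left side is always a named class."""

    named: Curie
    expr: ClassExpression


@dataclass(frozen=True)
class SubRoleOf:
    """Role hierarchy axiom ``sub SubPropertyOf sup``."""

    sub: Curie
    sup: Curie


@dataclass(frozen=True)
class RoleChain:
    """Binary role composition ``first o second SubPropertyOf sup``."""

    first: Curie
    second: Curie
    sup: Curie


Axiom = Union[SubClassOf, EquivalentTo, SubRoleOf, RoleChain]


def canonicalize_axiom(ax: Axiom) -> Axiom:
    if isinstance(ax, SubClassOf):
        return SubClassOf(canonicalize(ax.sub), canonicalize(ax.sup))
    if isinstance(ax, EquivalentTo):
        return EquivalentTo(ax.named, canonicalize(ax.expr))
    return ax


def axiom_signature(ax: Axiom) -> tuple[set[Curie], set[Curie]]:
    """Return (class ids, role ids) referenced by the axiom."""
    classes: set[Curie] = set()
    roles: set[Curie] = set()
    if isinstance(ax, SubClassOf):
        for expr in (ax.sub, ax.sup):
            for s in subexpressions(expr):
                if isinstance(s, Named):
                    classes.add(s.id)
                elif isinstance(s, Some):
                    roles.add(s.role)
    elif isinstance(ax, EquivalentTo):
        classes.add(ax.named)
        for s in subexpressions(ax.expr):
            if isinstance(s, Named):
                classes.add(s.id)
            elif isinstance(s, Some):
                roles.add(s.role)
    elif isinstance(ax, SubRoleOf):
        roles.update((ax.sub, ax.sup))
    else:
        roles.update((ax.first, ax.second, ax.sup))
    return classes, roles


# --------------------------------------------------------------------------
# Terms and ontologies
# --------------------------------------------------------------------------

SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")

#: Conventional label prefix for deprecated terms.
OBSOLETE_PREFIX = "obsolete "


@dataclass
class TermRecord:
    """Annotation record for one named class."""

    id: Curie
    label: str = ""
    definition: str = ""
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    deprecated: bool = False
    replaced_by: Optional[Curie] = None

    def exact_synonyms(self) -> list[str]:
        return [text for text, scope in self.synonyms if scope == "EXACT"]


@dataclass
class Ontology:
    """A small ontology: terms, roles, logical axioms, prefix map, subsets.

    ``subsets`` maps an OBO subset name (e.g. ``attribute_slim``) to the set
    of member classes; it is how the characteristics hierarchy marks which
    qualities are attribute-level (``amount``) as opposed to phenotypic
    states (``decreased amount``).
    """

    terms: dict[Curie, TermRecord] = field(default_factory=dict)
    roles: dict[Curie, str] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)
    prefixes: dict[str, str] = field(default_factory=default_prefixes)
    subsets: dict[str, set[Curie]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def add_term(self, id: Curie, label: str = "", **kwargs) -> TermRecord:
        rec = TermRecord(id=id, label=label, **kwargs)
        self.terms[id] = rec
        return rec

    def add_role(self, id: Curie, label: str = "") -> None:
        self.roles[id] = label

    def add_axiom(self, ax: Axiom) -> None:
        self.axioms.append(ax)

    def copy(self) -> "Ontology":
        return copy.deepcopy(self)

    def merge(self, other: "Ontology") -> "Ontology":
        """Return a new ontology with the union of both (other wins no
        annotation conflicts; axiom lists are concatenated, deduplicated on
        canonical form)."""
        out = self.copy()
        for cid, rec in other.terms.items():
            out.terms.setdefault(cid, copy.deepcopy(rec))
        for rid, label in other.roles.items():
            out.roles.setdefault(rid, label)
        seen = set(canonicalize_axiom(ax) for ax in out.axioms)
        for ax in other.axioms:
            c = canonicalize_axiom(ax)
            if c not in seen:
                seen.add(c)
                out.axioms.append(ax)
        for name, members in other.subsets.items():
            out.subsets.setdefault(name, set()).update(members)
        out.prefixes.update(other.prefixes)
        return out

    # -- queries -----------------------------------------------------------

    def live_terms(self) -> list[Curie]:
        return sorted((c for c, r in self.terms.items() if not r.deprecated),
                      key=str)

    def equiv_for(self, cid: Curie) -> Optional[EquivalentTo]:
        for ax in self.axioms:
            if isinstance(ax, EquivalentTo) and ax.named == cid:
                return ax
        return None

    def canonical_axiom_set(self) -> frozenset[Axiom]:
        return frozenset(canonicalize_axiom(ax) for ax in self.axioms)

    def label_of(self, cid: Curie) -> str:
        if cid in self.terms:
            return self.terms[cid].label or str(cid)
        if cid in self.roles:
            return self.roles[cid] or str(cid)
        return str(cid)

    def undeclared_references(self) -> list[Curie]:
        """Identifiers used in axioms but declared neither as terms nor
        roles (the DANGLING_REF QC input)."""
        missing: set[Curie] = set()
        for ax in self.axioms:
            classes, roles = axiom_signature(ax)
            for c in classes:
                if c not in self.terms and c != TOP.id:
                    missing.add(c)
            for r in roles:
                if r not in self.roles:
                    missing.add(r)
        return sorted(missing, key=str)

    def validate(self) -> None:
        """Enforce structural invariants; raise :class:`OntologyError`."""
        missing = self.undeclared_references()
        if missing:
            raise OntologyError(
                "axioms reference undeclared identifiers: "
                + ", ".join(map(str, missing)))
        seen_equiv: set[Curie] = set()
        for ax in self.axioms:
            if isinstance(ax, EquivalentTo):
                if ax.named in seen_equiv:
                    raise OntologyError(
                        f"more than one equivalence axiom for {ax.named}")
                seen_equiv.add(ax.named)


class IdMinter:
    """Sequential identifier minting for newly created trait terms.

    Mints ``prefix:NNNNNNN`` with a zero-padded 7-digit numeric local part,
    starting from a configured value.  Tagged locals (e.g. ``VT0000188``)
    originate from external vocabularies and are never minted here.
    """

    def __init__(self, prefix: str = "OBA", start: int = 9000001):
        self.prefix = prefix
        self._next = start

    def mint(self) -> Curie:
        cid = Curie(self.prefix, f"{self._next:07d}")
        self._next += 1
        return cid

    def mint_many(self, n: int) -> list[Curie]:
        return [self.mint() for _ in range(n)]
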