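"""Reader/writer for a subset of the OBO flat-file format.

Supported ``[Term]`` tags: id, name, def, synonym (with scope), subset,
is_a, relationship, intersection_of, is_obsolete, replaced_by.  Supported
``[Typedef]`` tags: id, name, is_a, holds_over_chain, is_transitive.

Semantics follow the standard OBO-to-OWL mapping for this subset:

* ``is_a: Y``                  → SubClassOf(C, Y)
* ``relationship: r Y``        → SubClassOf(C, r some Y)  (existential)
* the full set of ``intersection_of`` lines of a stanza
                               → one EquivalentTo(C, And(...))
* ``holds_over_chain: a b``    → RoleChain(a, b, r)
* ``is_transitive: true``      → RoleChain(r, r, r)

Obsolete stanzas must carry no logical tags: deprecated terms keep their
identifier and annotations only.  Unknown tags produce a warning and are
skipped; logical tags on an obsolete stanza are a hard error because they
violate the obsoletion convention.
"""

from __future__ import annotations

import re
import warnings
from typing import Optional

from ..model import (And, Curie, EquivalentTo, Named, Ontology, OntologyError,
                     RoleChain, Some, SubClassOf, SubRoleOf, SYNONYM_SCOPES,
                     default_prefixes, parse_curie)


class OboParseError(OntologyError):
    pass


_KNOWN_TERM_TAGS = {
    "id", "name", "def", "synonym", "subset", "is_a", "relationship",
    "intersection_of", "is_obsolete", "replaced_by",
}
_LOGICAL_TAGS = {"is_a", "relationship", "intersection_of"}
_KNOWN_TYPEDEF_TAGS = {"id", "name", "is_a", "holds_over_chain",
                       "is_transitive"}

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s+'
                         r'(?P<scope>EXACT|BROAD|NARROW|RELATED)\b')
_DEF_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _strip_comment(line: str) -> str:
    # OBO trailing comments start with " ! "
    idx = line.find(" ! ")
    if idx >= 0:
        return line[:idx]
    return line.rstrip(" !") if line.endswith(" !") else line


def _split_stanzas(text: str) -> tuple[list[str], list[tuple[str, list[tuple[str, str, int]]]]]:
    header: list[str] = []
    stanzas: list[tuple[str, list[tuple[str, str, int]]]] = []
    current: Optional[tuple[str, list[tuple[str, str, int]]]] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = (line[1:-1], [])
            stanzas.append(current)
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: malformed line {raw!r}")
        tag, value = line.split(":", 1)
        entry = (tag.strip(), value.strip(), lineno)
        if current is None:
            header.append(line)
        else:
            current[1].append(entry)
    return header, stanzas


def parse_obo(text: str, prefixes: Optional[dict[str, str]] = None) -> Ontology:
    """Parse OBO flat-file content into an :class:`Ontology`."""
    prefixes = prefixes if prefixes is not None else default_prefixes()
    ont = Ontology(prefixes=dict(prefixes))
    _, stanzas = _split_stanzas(text)
    for kind, entries in stanzas:
        if kind == "Term":
            _parse_term(ont, entries, prefixes)
        elif kind == "Typedef":
            _parse_typedef(ont, entries, prefixes)
        else:
            warnings.warn(f"skipping unknown stanza type [{kind}]")
    return ont


def _parse_term(ont: Ontology, entries, prefixes) -> None:
    cid: Optional[Curie] = None
    for tag, value, lineno in entries:
        if tag == "id":
            cid = parse_curie(value, prefixes)
            break
    if cid is None:
        raise OboParseError("[Term] stanza without id tag")
    rec = ont.add_term(cid)
    obsolete = any(tag == "is_obsolete" and value.lower() == "true"
                   for tag, value, _ in entries)
    rec.deprecated = obsolete
    if obsolete:
        bad = [tag for tag, _, _ in entries if tag in _LOGICAL_TAGS]
        if bad:
            raise OboParseError(
                f"obsolete term {cid} carries logical tags {sorted(set(bad))}; "
                "deprecated terms must have all logical axioms removed")

    intersections: list = []
    for tag, value, lineno in entries:
        if tag in ("id", "is_obsolete"):
            continue
        if tag == "name":
            rec.label = value
        elif tag == "def":
            m = _DEF_RE.match(value)
            if not m:
                raise OboParseError(f"line {lineno}: malformed def {value!r}")
            rec.definition = m.group("text").replace('\\"', '"')
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(
                    f"line {lineno}: malformed synonym {value!r} "
                    f"(expected scope in {SYNONYM_SCOPES})")
            rec.synonyms.append(
                (m.group("text").replace('\\"', '"'), m.group("scope")))
        elif tag == "subset":
            ont.subsets.setdefault(value, set()).add(cid)
        elif tag == "replaced_by":
            rec.replaced_by = parse_curie(value, prefixes)
        elif tag == "is_a":
            ont.add_axiom(SubClassOf(Named(cid),
                                     Named(parse_curie(value, prefixes))))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) != 2:
                raise OboParseError(
                    f"line {lineno}: malformed relationship {value!r}")
            role = parse_curie(parts[0], prefixes)
            filler = parse_curie(parts[1], prefixes)
            ont.add_axiom(SubClassOf(Named(cid), Some(role, Named(filler))))
        elif tag == "intersection_of":
            parts = value.split()
            if len(parts) == 1:
                intersections.append(Named(parse_curie(parts[0], prefixes)))
            elif len(parts) == 2:
                role = parse_curie(parts[0], prefixes)
                filler = parse_curie(parts[1], prefixes)
                intersections.append(Some(role, Named(filler)))
            else:
                raise OboParseError(
                    f"line {lineno}: malformed intersection_of {value!r}")
        else:
            warnings.warn(f"line {lineno}: skipping unknown tag {tag!r}")
    if intersections:
        if len(intersections) < 2:
            raise OboParseError(
                f"term {cid}: intersection_of requires at least two lines")
        ont.add_axiom(EquivalentTo(cid, And(tuple(intersections))))


def _parse_typedef(ont: Ontology, entries, prefixes) -> None:
    rid: Optional[Curie] = None
    for tag, value, _ in entries:
        if tag == "id":
            rid = parse_curie(value, prefixes)
            break
    if rid is None:
        raise OboParseError("[Typedef] stanza without id tag")
    ont.add_role(rid)
    for tag, value, lineno in entries:
        if tag == "id":
            continue
        if tag == "name":
            ont.roles[rid] = value
        elif tag == "is_a":
            ont.add_axiom(SubRoleOf(rid, parse_curie(value, prefixes)))
        elif tag == "holds_over_chain":
            parts = value.split()
            if len(parts) != 2:
                raise OboParseError(
                    f"line {lineno}: holds_over_chain needs exactly two roles")
            ont.add_axiom(RoleChain(parse_curie(parts[0], prefixes),
                                    parse_curie(parts[1], prefixes), rid))
        elif tag == "is_transitive":
            if value.lower() == "true":
                ont.add_axiom(RoleChain(rid, rid, rid))
        else:
            warnings.warn(f"line {lineno}: skipping unknown tag {tag!r}")


# --------------------------------------------------------------------------
# Writing (flat subset only)
# --------------------------------------------------------------------------


def write_obo(ont: Ontology, ontology_id: str = "eqtraits") -> str:
    """Serialise an ontology whose axioms fit the flat OBO subset.

    Axioms with nested expressions (anything beyond ``named``, ``r some
    named`` or an intersection of those) cannot be represented in OBO flat
    form and raise :class:`OntologyError`; use functional syntax for those.
    """
    lines = ["format-version: 1.2", f"ontology: {ontology_id}", ""]

    by_term: dict[Curie, list[str]] = {cid: [] for cid in ont.terms}
    role_lines: dict[Curie, list[str]] = {rid: [] for rid in ont.roles}

    def flat_operand(expr) -> str:
        if isinstance(expr, Named):
            return str(expr.id)
        if isinstance(expr, Some) and isinstance(expr.filler, Named):
            return f"{expr.role} {expr.filler.id}"
        raise OntologyError(
            f"expression {expr!r} is not representable in flat OBO")

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            if not isinstance(ax.sub, Named):
                raise OntologyError("GCIs are not representable in flat OBO")
            cid = ax.sub.id
            if isinstance(ax.sup, Named):
                by_term[cid].append(f"is_a: {ax.sup.id}")
            elif isinstance(ax.sup, Some) and isinstance(ax.sup.filler, Named):
                by_term[cid].append(
                    f"relationship: {ax.sup.role} {ax.sup.filler.id}")
            else:
                raise OntologyError(
                    f"superclass {ax.sup!r} is not representable in flat OBO")
        elif isinstance(ax, EquivalentTo):
            if not isinstance(ax.expr, And):
                raise OntologyError(
                    "equivalence to a non-intersection is not representable")
            for op in ax.expr.operands:
                by_term[ax.named].append(f"intersection_of: {flat_operand(op)}")
        elif isinstance(ax, SubRoleOf):
            role_lines[ax.sub].append(f"is_a: {ax.sup}")
        elif isinstance(ax, RoleChain):
            if ax.first == ax.second == ax.sup:
                role_lines[ax.sup].append("is_transitive: true")
            else:
                role_lines[ax.sup].append(
                    f"holds_over_chain: {ax.first} {ax.second}")

    subset_of: dict[Curie, list[str]] = {}
    for name in sorted(ont.subsets):
        for cid in ont.subsets[name]:
            subset_of.setdefault(cid, []).append(name)

    for cid in sorted(ont.terms, key=str):
        rec = ont.terms[cid]
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        if rec.label:
            lines.append(f"name: {rec.label}")
        if rec.definition:
            escaped = rec.definition.replace('"', '\\"')
            lines.append(f'def: "{escaped}" []')
        for text, scope in rec.synonyms:
            escaped = text.replace('"', '\\"')
            lines.append(f'synonym: "{escaped}" {scope} []')
        for name in sorted(subset_of.get(cid, [])):
            lines.append(f"subset: {name}")
        lines.extend(sorted(by_term.get(cid, [])))
        if rec.deprecated:
            lines.append("is_obsolete: true")
        if rec.replaced_by is not None:
            lines.append(f"replaced_by: {rec.replaced_by}")
        lines.append("")

    for rid in sorted(ont.roles, key=str):
        lines.append("[Typedef]")
        lines.append(f"id: {rid}")
        if ont.roles[rid]:
            lines.append(f"name: {ont.roles[rid]}")
        lines.extend(sorted(role_lines.get(rid, [])))
        lines.append("")

    return "\n".join(lines).rstrip() + "\n"
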