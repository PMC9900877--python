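"""OWL functional-syntax reader/writer for the supported EL fragment.

The writer is the canonical logical serialisation of this package: output
is deterministic (sorted by identifier) and ``parse ∘ write`` preserves the
canonical axiom set.  The parser accepts exactly the constructs the writer
emits plus whitespace variation; anything else (unions, complements,
universal restrictions, …) is rejected with the offending token and its
position.
"""

from __future__ import annotations

import re
from typing import Optional

from ..model import (And, ClassExpression, Curie, EquivalentTo, Named,
                     Ontology, OntologyError, RoleChain, Some, SubClassOf,
                     SubRoleOf, TermRecord, UnsupportedConstructError,
                     default_prefixes, parse_curie)


class FunctionalSyntaxError(OntologyError):
    pass


_LABEL_PROP = "rdfs:label"
_DEFINITION_PROP = "IAO:0000115"
_REPLACED_BY_PROP = "IAO:0100001"
_DEPRECATED_PROP = "owl:deprecated"
_SYNONYM_PROPS = {
    "EXACT": "oboInOwl:hasExactSynonym",
    "BROAD": "oboInOwl:hasBroadSynonym",
    "NARROW": "oboInOwl:hasNarrowSynonym",
    "RELATED": "oboInOwl:hasRelatedSynonym",
}
_SYNONYM_SCOPE_BY_PROP = {v: k for k, v in _SYNONYM_PROPS.items()}
_SUBSET_PROP = "oboInOwl:inSubset"


def _render_expr(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return str(expr.id)
    if isinstance(expr, Some):
        return (f"ObjectSomeValuesFrom({expr.role} "
                f"{_render_expr(expr.filler)})")
    inner = " ".join(_render_expr(op) for op in expr.operands)
    return f"ObjectIntersectionOf({inner})"


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_functional_syntax(ont: Ontology,
                            ontology_iri: str = "http://example.org/eqtraits"
                            ) -> str:
    """Serialise deterministically to OWL functional syntax."""
    lines: list[str] = []
    for prefix in sorted(ont.prefixes):
        lines.append(f"Prefix({prefix}:=<{ont.prefixes[prefix]}>)")
    lines.append(f"Ontology(<{ontology_iri}>")

    for rid in sorted(ont.roles, key=str):
        lines.append(f"Declaration(ObjectProperty({rid}))")
        if ont.roles[rid]:
            lines.append(f"AnnotationAssertion({_LABEL_PROP} {rid} "
                         f"{_quote(ont.roles[rid])})")
    subset_of: dict[Curie, list[str]] = {}
    for name in sorted(ont.subsets):
        for cid in ont.subsets[name]:
            subset_of.setdefault(cid, []).append(name)
    for cid in sorted(ont.terms, key=str):
        rec = ont.terms[cid]
        lines.append(f"Declaration(Class({cid}))")
        if rec.label:
            lines.append(f"AnnotationAssertion({_LABEL_PROP} {cid} "
                         f"{_quote(rec.label)})")
        if rec.definition:
            lines.append(f"AnnotationAssertion({_DEFINITION_PROP} {cid} "
                         f"{_quote(rec.definition)})")
        for text, scope in sorted(rec.synonyms):
            lines.append(f"AnnotationAssertion({_SYNONYM_PROPS[scope]} {cid} "
                         f"{_quote(text)})")
        for name in sorted(subset_of.get(cid, [])):
            lines.append(f"AnnotationAssertion({_SUBSET_PROP} {cid} "
                         f"{_quote(name)})")
        if rec.deprecated:
            lines.append(f"AnnotationAssertion({_DEPRECATED_PROP} {cid} "
                         f'"true"^^xsd:boolean)')
        if rec.replaced_by is not None:
            lines.append(f"AnnotationAssertion({_REPLACED_BY_PROP} {cid} "
                         f"{rec.replaced_by})")

    rendered: list[str] = []
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            rendered.append(f"SubClassOf({_render_expr(ax.sub)} "
                            f"{_render_expr(ax.sup)})")
        elif isinstance(ax, EquivalentTo):
            rendered.append(f"EquivalentClasses({ax.named} "
                            f"{_render_expr(ax.expr)})")
        elif isinstance(ax, SubRoleOf):
            rendered.append(f"SubObjectPropertyOf({ax.sub} {ax.sup})")
        elif isinstance(ax, RoleChain):
            rendered.append(
                f"SubObjectPropertyOf(ObjectPropertyChain({ax.first} "
                f"{ax.second}) {ax.sup})")
    lines.extend(sorted(set(rendered)))
    lines.append(")")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<string>"(?:[^"\\]|\\.)*"(?:\^\^[A-Za-z0-9:]+)?)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<atom>[^\s()]+)
    """, re.VERBOSE)

_REJECTED_CONSTRUCTS = {
    "ObjectUnionOf", "ObjectComplementOf", "ObjectAllValuesFrom",
    "ObjectOneOf", "ObjectHasValue", "ObjectHasSelf", "ObjectMinCardinality",
    "ObjectMaxCardinality", "ObjectExactCardinality", "DisjointClasses",
    "DataSomeValuesFrom", "DataPropertyAssertion",
}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for m in _TOKEN_RE.finditer(line):
            kind = m.lastgroup
            tokens.append((kind, m.group(), lineno))
    return tokens


class _OfnParser:
    def __init__(self, tokens, prefixes):
        self.tokens = tokens
        self.pos = 0
        self.prefixes = prefixes

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, expected_kind: Optional[str] = None):
        tok = self.peek()
        if tok is None:
            raise FunctionalSyntaxError("unexpected end of document")
        if expected_kind and tok[0] != expected_kind:
            raise FunctionalSyntaxError(
                f"line {tok[2]}: expected {expected_kind}, found {tok[1]!r}")
        self.pos += 1
        return tok

    def expect_atom(self, value: str):
        tok = self.take("atom")
        if tok[1] != value:
            raise FunctionalSyntaxError(
                f"line {tok[2]}: expected {value!r}, found {tok[1]!r}")

    def parse_curie_token(self) -> Curie:
        tok = self.take("atom")
        text = tok[1]
        if text.startswith("<") and text.endswith(">"):
            text = text[1:-1]
        try:
            return parse_curie(text, self.prefixes)
        except OntologyError as exc:
            raise FunctionalSyntaxError(f"line {tok[2]}: {exc}") from exc

    def parse_expr(self) -> ClassExpression:
        tok = self.peek()
        if tok is None:
            raise FunctionalSyntaxError("unexpected end of document")
        if tok[0] == "atom" and tok[1] == "ObjectIntersectionOf":
            self.take()
            self.take("lparen")
            operands = []
            while self.peek() and self.peek()[0] != "rparen":
                operands.append(self.parse_expr())
            self.take("rparen")
            if len(operands) < 2:
                raise FunctionalSyntaxError(
                    f"line {tok[2]}: ObjectIntersectionOf needs >=2 operands")
            return And(tuple(operands))
        if tok[0] == "atom" and tok[1] == "ObjectSomeValuesFrom":
            self.take()
            self.take("lparen")
            role = self.parse_curie_token()
            filler = self.parse_expr()
            self.take("rparen")
            return Some(role, filler)
        if tok[0] == "atom" and tok[1] in _REJECTED_CONSTRUCTS:
            raise UnsupportedConstructError(
                f"line {tok[2]}: {tok[1]} is outside the supported EL "
                "fragment")
        return Named(self.parse_curie_token())


def parse_functional_syntax(text: str,
                            prefixes: Optional[dict[str, str]] = None
                            ) -> Ontology:
    """Parse the functional-syntax subset emitted by
    :func:`write_functional_syntax`."""
    declared_prefixes = dict(prefixes) if prefixes else {}
    for m in re.finditer(r"Prefix\(([A-Za-z][\w]*):=<([^>]*)>\)", text):
        declared_prefixes[m.group(1)] = m.group(2)
    if not declared_prefixes:
        declared_prefixes = default_prefixes()
    body_start = text.find("Ontology(")
    if body_start < 0:
        raise FunctionalSyntaxError("no Ontology(...) block found")
    body = text[body_start + len("Ontology("):]
    # drop the final closing paren of the Ontology block
    body = body.rstrip()
    if not body.endswith(")"):
        raise FunctionalSyntaxError("unterminated Ontology(...) block")
    body = body[:-1]
    # drop an optional ontology IRI
    body = re.sub(r"^\s*<[^>]*>", "", body, count=1)

    ont = Ontology(prefixes=declared_prefixes)
    parser = _OfnParser(_tokenize(body), declared_prefixes)

    def ensure_term(cid: Curie) -> TermRecord:
        if cid not in ont.terms:
            ont.add_term(cid)
        return ont.terms[cid]

    while parser.peek() is not None:
        tok = parser.take("atom")
        keyword, lineno = tok[1], tok[2]
        if keyword == "Declaration":
            parser.take("lparen")
            kind = parser.take("atom")[1]
            parser.take("lparen")
            cid = parser.parse_curie_token()
            parser.take("rparen")
            parser.take("rparen")
            if kind == "Class":
                ensure_term(cid)
            elif kind == "ObjectProperty":
                ont.roles.setdefault(cid, "")
            else:
                raise UnsupportedConstructError(
                    f"line {lineno}: Declaration({kind}) is unsupported")
        elif keyword == "AnnotationAssertion":
            parser.take("lparen")
            prop = parser.take("atom")[1]
            subject = parser.parse_curie_token()
            value_tok = parser.take()
            parser.take("rparen")
            _apply_annotation(ont, ensure_term, prop, subject, value_tok,
                              declared_prefixes)
        elif keyword == "SubClassOf":
            parser.take("lparen")
            sub = parser.parse_expr()
            sup = parser.parse_expr()
            parser.take("rparen")
            ont.add_axiom(SubClassOf(sub, sup))
        elif keyword == "EquivalentClasses":
            parser.take("lparen")
            first = parser.parse_expr()
            second = parser.parse_expr()
            parser.take("rparen")
            if isinstance(first, Named):
                ont.add_axiom(EquivalentTo(first.id, second))
            elif isinstance(second, Named):
                ont.add_axiom(EquivalentTo(second.id, first))
            else:
                raise UnsupportedConstructError(
                    f"line {lineno}: EquivalentClasses requires one named "
                    "side")
        elif keyword == "SubObjectPropertyOf":
            parser.take("lparen")
            nxt = parser.peek()
            if nxt[0] == "atom" and nxt[1] == "ObjectPropertyChain":
                parser.take()
                parser.take("lparen")
                first = parser.parse_curie_token()
                second = parser.parse_curie_token()
                if parser.peek()[0] != "rparen":
                    raise UnsupportedConstructError(
                        f"line {lineno}: only binary property chains are "
                        "supported")
                parser.take("rparen")
                sup = parser.parse_curie_token()
                parser.take("rparen")
                ont.add_axiom(RoleChain(first, second, sup))
            else:
                sub = parser.parse_curie_token()
                sup = parser.parse_curie_token()
                parser.take("rparen")
                ont.add_axiom(SubRoleOf(sub, sup))
        elif keyword in _REJECTED_CONSTRUCTS:
            raise UnsupportedConstructError(
                f"line {lineno}: {keyword} is outside the supported EL "
                "fragment")
        else:
            raise FunctionalSyntaxError(
                f"line {lineno}: unsupported construct {keyword!r}")
    return ont


def _unquote(literal: str) -> str:
    literal = re.sub(r"\^\^[A-Za-z0-9:]+$", "", literal)
    if literal.startswith('"') and literal.endswith('"'):
        literal = literal[1:-1]
    return literal.replace('\\"', '"').replace("\\\\", "\\")


def _apply_annotation(ont, ensure_term, prop, subject, value_tok, prefixes):
    kind, raw, lineno = value_tok
    if prop == _LABEL_PROP:
        if subject in ont.roles:
            ont.roles[subject] = _unquote(raw)
        else:
            ensure_term(subject).label = _unquote(raw)
    elif prop == _DEFINITION_PROP:
        ensure_term(subject).definition = _unquote(raw)
    elif prop in _SYNONYM_SCOPE_BY_PROP:
        ensure_term(subject).synonyms.append(
            (_unquote(raw), _SYNONYM_SCOPE_BY_PROP[prop]))
    elif prop == _SUBSET_PROP:
        ont.subsets.setdefault(_unquote(raw), set()).add(subject)
    elif prop == _DEPRECATED_PROP:
        ensure_term(subject).deprecated = _unquote(raw) == "true"
    elif prop == _REPLACED_BY_PROP:
        ensure_term(subject).replaced_by = parse_curie(raw, prefixes)
    else:
        raise FunctionalSyntaxError(
            f"line {lineno}: unsupported annotation property {prop!r}")
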