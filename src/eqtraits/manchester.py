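"""A Manchester-like surface syntax for EL class expressions.

Grammar (only the EL constructors are accepted)::

    expr    := conj
    conj    := primary ("and" primary)*
    primary := CURIE | CURIE "some" primary | "(" expr ")"

``or``, ``not``, ``only``, ``value``, ``min``, ``max`` and ``exactly`` are
recognised keywords and rejected with an explicit error, so that input
beyond the supported profile fails loudly instead of being misread.
"""

from __future__ import annotations

import re
from typing import Optional

from .model import (And, ClassExpression, Curie, Named, OntologyError, Some,
                    UnsupportedConstructError, canonicalize, default_prefixes,
                    parse_curie)


class ExpressionParseError(OntologyError):
    pass


_REJECTED = {"or", "not", "only", "value", "min", "max", "exactly", "self"}

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text)


class _Parser:
    def __init__(self, tokens: list[str], prefixes: dict[str, str]):
        self.tokens = tokens
        self.pos = 0
        self.prefixes = prefixes

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse_expr(self) -> ClassExpression:
        operands = [self.parse_primary()]
        while self.peek() == "and":
            self.take()
            operands.append(self.parse_primary())
        if self.peek() in _REJECTED:
            raise UnsupportedConstructError(
                f"construct {self.peek()!r} is outside the EL fragment "
                f"(token {self.pos})")
        if len(operands) == 1:
            return operands[0]
        return And(tuple(operands))

    def parse_primary(self) -> ClassExpression:
        tok = self.take()
        if tok == "(":
            inner = self.parse_expr()
            closing = self.take()
            if closing != ")":
                raise ExpressionParseError(
                    f"expected ')', found {closing!r} (token {self.pos})")
            return inner
        if tok in _REJECTED:
            raise UnsupportedConstructError(
                f"construct {tok!r} is outside the EL fragment "
                f"(token {self.pos})")
        if tok in ("and", "some", ")"):
            raise ExpressionParseError(
                f"unexpected {tok!r} (token {self.pos})")
        curie = parse_curie(tok, self.prefixes)
        if self.peek() == "some":
            self.take()
            filler = self.parse_primary()
            return Some(curie, filler)
        return Named(curie)


def parse_class_expression(text: str,
                           prefixes: Optional[dict[str, str]] = None
                           ) -> ClassExpression:
    """Parse ``text`` into a canonical EL class expression."""
    prefixes = prefixes if prefixes is not None else default_prefixes()
    tokens = tokenize(text)
    if not tokens:
        raise ExpressionParseError("empty class expression")
    parser = _Parser(tokens, prefixes)
    expr = parser.parse_expr()
    if parser.peek() is not None:
        raise ExpressionParseError(
            f"trailing input starting at {parser.peek()!r} "
            f"(token {parser.pos})")
    return canonicalize(expr)


def render_class_expression(expr: ClassExpression) -> str:
    """Inverse of :func:`parse_class_expression` (modulo canonical order)."""
    if isinstance(expr, Named):
        return str(expr.id)
    if isinstance(expr, Some):
        filler = render_class_expression(expr.filler)
        if isinstance(expr.filler, (And, Some)):
            filler = f"({filler})"
        return f"{expr.role} some {filler}"
    parts = []
    for op in expr.operands:
        text = render_class_expression(op)
        if isinstance(op, (And, Some)):
            text = f"({text})"
        parts.append(text)
    return " and ".join(parts)
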