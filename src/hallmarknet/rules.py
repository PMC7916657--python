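"""Boolean expression trees and the BoolNet text dialect.

Expressions are immutable trees over node identifiers with AND, OR, NOT and
the constants 0/1. The serialized form follows the widespread "targets,
factors" rules dialect: ``!`` for NOT, ``&`` for AND, ``|`` for OR,
parentheses for grouping, ``0``/``1`` for constants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def __repr__(self) -> str:
        return format_expr(self)


@dataclass(frozen=True, repr=False)
class Var(Expr):
    name: str

    def evaluate(self, state: Mapping[str, int]) -> int:
        return int(state[self.name])

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})


@dataclass(frozen=True, repr=False)
class Const(Expr):
    value: int  # 0 or 1

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.value

    def variables(self) -> frozenset[str]:
        return frozenset()


@dataclass(frozen=True, repr=False)
class Not(Expr):
    operand: Expr

    def evaluate(self, state: Mapping[str, int]) -> int:
        return 1 - self.operand.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.operand.variables()


@dataclass(frozen=True, repr=False)
class And(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, state: Mapping[str, int]) -> int:
        return int(all(o.evaluate(state) for o in self.operands))

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(o.variables() for o in self.operands))


@dataclass(frozen=True, repr=False)
class Or(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, state: Mapping[str, int]) -> int:
        return int(any(o.evaluate(state) for o in self.operands))

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(o.variables() for o in self.operands))


TRUE = Const(1)
FALSE = Const(0)


def any_of(names_or_exprs) -> Expr:
    """OR over operands; a single operand is returned unwrapped."""
    ops = tuple(Var(x) if isinstance(x, str) else x for x in names_or_exprs)
    if not ops:
        raise ValueError("any_of requires at least one operand")
    return ops[0] if len(ops) == 1 else Or(ops)


def all_of(names_or_exprs) -> Expr:
    ops = tuple(Var(x) if isinstance(x, str) else x for x in names_or_exprs)
    if not ops:
        raise ValueError("all_of requires at least one operand")
    return ops[0] if len(ops) == 1 else And(ops)


# ---------------------------------------------------------------------------
# Formatting (BoolNet "factors" column)
# ---------------------------------------------------------------------------

def format_expr(expr: Expr, _parent_prec: int = 0) -> str:
    """Render an expression in the rules dialect. OR binds loosest, then AND, then NOT."""
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        inner = format_expr(expr.operand, 3)
        return f"!{inner}"
    if isinstance(expr, And):
        s = " & ".join(format_expr(o, 2) for o in expr.operands)
        return f"({s})" if _parent_prec > 1 else s
    if isinstance(expr, Or):
        s = " | ".join(format_expr(o, 1) for o in expr.operands)
        return f"({s})" if _parent_prec > 0 else s
    raise TypeError(f"unknown expression node {type(expr).__name__}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][\w.\-]*)|([01])|([!&|()]))")


class ExprParseError(ValueError):
    pass


def _tokenize(text: str) -> Iterator[tuple[str, str]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExprParseError(f"unexpected character at {text[pos:]!r}")
            return
        if m.group(1):
            yield ("name", m.group(1))
        elif m.group(2):
            yield ("const", m.group(2))
        else:
            yield ("op", m.group(3))
        pos = m.end()


def parse_expr(text: str) -> Expr:
    """Parse the rules dialect into an expression tree.

    Grammar: or-expr := and-expr ('|' and-expr)*; and-expr := unary ('&' unary)*;
    unary := '!' unary | '(' or-expr ')' | name | 0 | 1.
    """
    tokens = list(_tokenize(text))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or() -> Expr:
        ops = [parse_and()]
        while peek() == ("op", "|"):
            take()
            ops.append(parse_and())
        return ops[0] if len(ops) == 1 else Or(tuple(ops))

    def parse_and() -> Expr:
        ops = [parse_unary()]
        while peek() == ("op", "&"):
            take()
            ops.append(parse_unary())
        return ops[0] if len(ops) == 1 else And(tuple(ops))

    def parse_unary() -> Expr:
        kind, value = take()
        if kind == "op" and value == "!":
            return Not(parse_unary())
        if kind == "op" and value == "(":
            inner = parse_or()
            kind2, value2 = take()
            if (kind2, value2) != ("op", ")"):
                raise ExprParseError(f"expected ')' in {text!r}")
            return inner
        if kind == "name":
            return Var(value)
        if kind == "const":
            return Const(int(value))
        raise ExprParseError(f"unexpected token {value!r} in {text!r}")

    result = parse_or()
    if pos != len(tokens):
        raise ExprParseError(f"trailing tokens in {text!r}")
    return result
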