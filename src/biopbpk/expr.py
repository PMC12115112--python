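"""Arithmetic expression language with index specifiers.

Rate and assignment expressions in the model-description language are plain
arithmetic over symbol references, e.g. ``P[i=thisInstance]*S1``.  A symbol may
carry an *index specifier* in square brackets selecting one component of an
indexed quantity array:

* ``Q[i=$A]``  — literal: select the component at index value ``A``;
* ``Q[i=name]`` — placeholder: the value is looked up in the binding
  environment (an index-value node such as ``thisOrgan``).

Supported operators: ``+ - * / ^`` (also ``**``), unary minus, parentheses.
Supported functions: ``exp``, ``expm1``, ``log``, ``sqrt``, ``abs``, ``min``,
``max``, and ``pef`` (the two-pore Peclet factor x/(e^x - 1), equal to 1 at
x = 0).  The symbols ``t`` and ``time`` denote simulation time.

The module provides parsing to a small immutable AST, symbol substitution,
direct evaluation against a name->value environment, and unparsing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping

__all__ = [
    "ExpressionError",
    "Num",
    "Sym",
    "Bin",
    "Neg",
    "Call",
    "parse",
    "unparse",
    "evaluate",
    "map_symbols",
    "symbols",
    "FUNCTIONS",
    "TIME_NAMES",
]


class ExpressionError(ValueError):
    """Raised for syntax errors or evaluation failures in expressions."""


def pef(x: float) -> float:
    """Peclet factor ``x / (exp(x) - 1)``; continuous value 1.0 at x = 0."""
    if x == 0.0:
        return 1.0
    if x > 700.0:  # exp would overflow; the factor is numerically zero
        return 0.0
    return x / math.expm1(x)


FUNCTIONS: dict[str, Callable] = {
    "exp": math.exp,
    "expm1": math.expm1,
    "log": math.log,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "pef": pef,
}

TIME_NAMES = ("t", "time")


# --------------------------------------------------------------------------- AST

@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Sym:
    """Symbol reference; ``spec`` is a tuple of (index, value, is_literal)."""

    name: str
    spec: tuple = ()


@dataclass(frozen=True)
class Bin:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class Neg:
    arg: object


@dataclass(frozen=True)
class Call:
    fn: str
    args: tuple


# --------------------------------------------------------------------- tokenizer

_TOKEN = re.compile(
    r"""\s*(?:
        (?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
       |(?P<name>\$?[A-Za-z_][A-Za-z0-9_.]*)
       |(?P<op>\*\*|[-+*/^()\[\],=])
    )""",
    re.X,
)

_NORMALIZE = str.maketrans({"∗": "*", "−": "-", "·": "*", "×": "*"})


def _tokenize(text: str) -> list[tuple[str, str]]:
    text = text.translate(_NORMALIZE)
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"unrecognised token at {rest[:20]!r}")
        pos = m.end()
        for kind in ("num", "name", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
    return tokens


# ------------------------------------------------------------------------ parser

class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression in {self.text!r}")
        self.pos += 1
        return tok

    def expect(self, value: str) -> None:
        kind, tok = self.next()
        if tok != value:
            raise ExpressionError(f"expected {value!r}, found {tok!r} in {self.text!r}")

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ExpressionError(f"trailing input {self.peek()[1]!r} in {self.text!r}")
        return node

    def expr(self):
        node = self.term()
        while (tok := self.peek()) and tok[1] in "+-" and tok[0] == "op":
            self.next()
            node = Bin(tok[1], node, self.term())
        return node

    def term(self):
        node = self.unary()
        while (tok := self.peek()) and tok[1] in "*/" and tok[0] == "op":
            self.next()
            node = Bin(tok[1], node, self.unary())
        return node

    def unary(self):
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in "+-":
            self.next()
            arg = self.unary()
            return arg if tok[1] == "+" else Neg(arg)
        return self.power()

    def power(self):
        base = self.atom()
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in ("^", "**"):
            self.next()
            return Bin("^", base, self.unary())  # right-associative
        return base

    def atom(self):
        kind, tok = self.next()
        if kind == "num":
            return Num(float(tok))
        if kind == "op" and tok == "(":
            node = self.expr()
            self.expect(")")
            return node
        if kind == "name":
            if tok.startswith("$"):
                raise ExpressionError(f"'$' only allowed inside [..] specifiers: {tok!r}")
            nxt = self.peek()
            if nxt and nxt[1] == "(" and tok in FUNCTIONS:
                self.next()
                args = [self.expr()]
                while self.peek() and self.peek()[1] == ",":
                    self.next()
                    args.append(self.expr())
                self.expect(")")
                return Call(tok, tuple(args))
            spec = ()
            if nxt and nxt[1] == "[":
                spec = self._specifier()
            return Sym(tok, spec)
        raise ExpressionError(f"unexpected token {tok!r} in {self.text!r}")

    def _specifier(self) -> tuple:
        self.expect("[")
        entries = []
        while True:
            kind, idx = self.next()
            if kind != "name":
                raise ExpressionError(f"bad index name {idx!r} in specifier")
            self.expect("=")
            kind, val = self.next()
            if kind != "name":
                raise ExpressionError(f"bad index value {val!r} in specifier")
            if val.startswith("$"):
                entries.append((idx, val[1:], True))
            else:
                entries.append((idx, val, False))
            kind, tok = self.next()
            if tok == "]":
                break
            if tok != ",":
                raise ExpressionError(f"expected ',' or ']' in specifier, found {tok!r}")
        return tuple(entries)


def parse(text: str):
    """Parse expression text into an AST node."""
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError(f"empty expression: {text!r}")
    return _Parser(_tokenize(text), text).parse()


# --------------------------------------------------------------------- utilities

def symbols(node) -> Iterator[Sym]:
    """Yield every symbol reference in the tree (depth-first, left to right)."""
    if isinstance(node, Sym):
        yield node
    elif isinstance(node, Bin):
        yield from symbols(node.left)
        yield from symbols(node.right)
    elif isinstance(node, Neg):
        yield from symbols(node.arg)
    elif isinstance(node, Call):
        for a in node.args:
            yield from symbols(a)


def map_symbols(node, fn: Callable[[Sym], object]):
    """Return a new tree with every ``Sym`` replaced by ``fn(sym)``."""
    if isinstance(node, Sym):
        return fn(node)
    if isinstance(node, Bin):
        return Bin(node.op, map_symbols(node.left, fn), map_symbols(node.right, fn))
    if isinstance(node, Neg):
        return Neg(map_symbols(node.arg, fn))
    if isinstance(node, Call):
        return Call(node.fn, tuple(map_symbols(a, fn) for a in node.args))
    return node


def evaluate(node, env: Mapping[str, float], t: float = 0.0) -> float:
    """Evaluate a resolved tree against a name->value environment."""
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Sym):
        if node.spec:
            raise ExpressionError(f"unresolved specifier on {node.name!r}")
        if node.name in TIME_NAMES and node.name not in env:
            return t
        try:
            return float(env[node.name])
        except KeyError:
            raise ExpressionError(f"unknown symbol {node.name!r}") from None
    if isinstance(node, Bin):
        a = evaluate(node.left, env, t)
        b = evaluate(node.right, env, t)
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        if node.op == "*":
            return a * b
        if node.op == "/":
            return a / b
        if node.op == "^":
            return a ** b
        raise ExpressionError(f"unknown operator {node.op!r}")
    if isinstance(node, Neg):
        return -evaluate(node.arg, env, t)
    if isinstance(node, Call):
        return FUNCTIONS[node.fn](*(evaluate(a, env, t) for a in node.args))
    raise ExpressionError(f"cannot evaluate {node!r}")


def _spec_text(spec: tuple) -> str:
    if not spec:
        return ""
    parts = [f"{i}=${v}" if lit else f"{i}={v}" for i, v, lit in spec]
    return "[" + ",".join(parts) + "]"


def unparse(node, _parent_prec: int = 0) -> str:
    """Render a tree back to expression text (minimal parenthesisation)."""
    prec = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 3}
    if isinstance(node, Num):
        v = node.value
        return repr(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)
    if isinstance(node, Sym):
        return node.name + _spec_text(node.spec)
    if isinstance(node, Neg):
        inner = unparse(node.arg, 4)
        return f"-{inner}"
    if isinstance(node, Call):
        return f"{node.fn}({', '.join(unparse(a) for a in node.args)})"
    if isinstance(node, Bin):
        p = prec[node.op]
        left = unparse(node.left, p)
        right = unparse(node.right, p + 1)
        text = f"{left}{node.op}{right}" if node.op in "*/^" else f"{left} {node.op} {right}"
        return f"({text})" if p < _parent_prec else text
    raise ExpressionError(f"cannot unparse {node!r}")
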