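"""C-style mathematical expressions used inside MathInline elements.

Time derivatives, triggers, state assignments and aliases in the component
layer are all plain-text formulae such as ``(v_rest - v)/tau_m`` or
``t > t_spike + tau_refractory``.  This module parses them into small
expression trees, reports the free symbols, and evaluates them against an
environment of bound values.  Evaluation is polymorphic over scalars and
numpy arrays, so a single tree can be applied to a whole instance set at
once.

Grammar (precedence low to high, matching C):

    or        :=  and ( '||' and )*
    and       :=  not ( '&&' not )*
    not       :=  '!' not | comparison
    comparison:=  sum ( ('>'|'<'|'>='|'<='|'=='|'!=') sum )?
    sum       :=  term ( ('+'|'-') term )*
    term      :=  unary ( ('*'|'/') unary )*
    unary     :=  '-' unary | atom
    atom      :=  NUMBER | NAME | NAME '(' args ')' | '(' or ')'

Boolean operators are legal only in trigger contexts; the component
validator enforces that restriction, not the parser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Union

import numpy as np

__all__ = [
    "ExpressionError",
    "EvaluationError",
    "Node",
    "Num",
    "Sym",
    "Unary",
    "Binary",
    "Call",
    "ExpressionTree",
    "parse_expression",
    "evaluate",
    "free_symbols",
    "serialize",
    "FUNCTIONS",
]


class ExpressionError(ValueError):
    """Syntax error in an expression; carries the character offset."""

    def __init__(self, message: str, source: str, offset: int):
        super().__init__(f"{message} at offset {offset} in {source!r}")
        self.source = source
        self.offset = offset


class EvaluationError(ValueError):
    """Unbound symbol or numeric-domain failure during evaluation."""


# ---------------------------------------------------------------------------
# AST nodes


@dataclass(frozen=True)
class Num:
    value: float

    def __str__(self) -> str:
        return repr(self.value) if self.value != int(self.value) else str(int(self.value))


@dataclass(frozen=True)
class Sym:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Unary:
    op: str  # '-' or '!'
    operand: "Node"

    def __str__(self) -> str:
        return f"{self.op}({self.operand})"


@dataclass(frozen=True)
class Binary:
    op: str
    left: "Node"
    right: "Node"

    def __str__(self) -> str:
        return f"({self.left} {self.op} {self.right})"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["Node", ...]

    def __str__(self) -> str:
        return f"{self.func}({', '.join(str(a) for a in self.args)})"


Node = Union[Num, Sym, Unary, Binary, Call]


@dataclass(frozen=True)
class ExpressionTree:
    """A parsed expression: the tree root plus the text it came from."""

    root: Node
    source_text: str

    def __str__(self) -> str:
        return serialize(self)


# name -> (arity, numpy ufunc).  'log' and 'ln' are both natural log, as in C
# only 'log' exists; modelling dialects commonly accept both spellings.
FUNCTIONS: dict[str, tuple[int, Callable]] = {
    "exp": (1, np.exp),
    "log": (1, np.log),
    "ln": (1, np.log),
    "sin": (1, np.sin),
    "cos": (1, np.cos),
    "sqrt": (1, np.sqrt),
    "pow": (2, np.power),
    "fabs": (1, np.fabs),
}

_COMPARISONS = {">", "<", ">=", "<=", "==", "!="}
_BOOLEAN_OPS = {"&&", "||", "!"}


# ---------------------------------------------------------------------------
# Tokenizer


@dataclass
class _Token:
    kind: str  # 'num' | 'name' | 'op'
    text: str
    pos: int


_TWO_CHAR_OPS = (">=", "<=", "==", "!=", "&&", "||")
_ONE_CHAR_OPS = "+-*/()<>!,"


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            # exponent part
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            try:
                float(text[i:j])
            except ValueError:
                raise ExpressionError("malformed number", text, i)
            tokens.append(_Token("num", text[i:j], i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(_Token("name", text[i:j], i))
            i = j
            continue
        if text[i : i + 2] in _TWO_CHAR_OPS:
            tokens.append(_Token("op", text[i : i + 2], i))
            i += 2
            continue
        if c in _ONE_CHAR_OPS:
            tokens.append(_Token("op", c, i))
            i += 1
            continue
        raise ExpressionError(f"unexpected character {c!r}", text, i)
    return tokens


# ---------------------------------------------------------------------------
# Parser


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression", self.text, len(self.text))
        self.i += 1
        return tok

    def expect(self, op: str) -> None:
        tok = self.peek()
        if tok is None or tok.kind != "op" or tok.text != op:
            pos = tok.pos if tok else len(self.text)
            raise ExpressionError(f"expected {op!r}", self.text, pos)
        self.i += 1

    def at_op(self, *ops: str) -> str | None:
        tok = self.peek()
        if tok is not None and tok.kind == "op" and tok.text in ops:
            return tok.text
        return None

    # precedence ladder ----------------------------------------------------

    def parse(self) -> Node:
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise ExpressionError(f"trailing input {tok.text!r}", self.text, tok.pos)
        return node

    def parse_or(self) -> Node:
        node = self.parse_and()
        while self.at_op("||"):
            self.next()
            node = Binary("||", node, self.parse_and())
        return node

    def parse_and(self) -> Node:
        node = self.parse_not()
        while self.at_op("&&"):
            self.next()
            node = Binary("&&", node, self.parse_not())
        return node

    def parse_not(self) -> Node:
        if self.at_op("!"):
            self.next()
            return Unary("!", self.parse_not())
        return self.parse_comparison()

    def parse_comparison(self) -> Node:
        node = self.parse_sum()
        op = self.at_op(*_COMPARISONS)
        if op:
            self.next()
            node = Binary(op, node, self.parse_sum())
        return node

    def parse_sum(self) -> Node:
        node = self.parse_term()
        while True:
            op = self.at_op("+", "-")
            if not op:
                return node
            self.next()
            node = Binary(op, node, self.parse_term())

    def parse_term(self) -> Node:
        node = self.parse_unary()
        while True:
            op = self.at_op("*", "/")
            if not op:
                return node
            self.next()
            node = Binary(op, node, self.parse_unary())

    def parse_unary(self) -> Node:
        if self.at_op("-"):
            self.next()
            return Unary("-", self.parse_unary())
        return self.parse_atom()

    def parse_atom(self) -> Node:
        tok = self.next()
        if tok.kind == "num":
            return Num(float(tok.text))
        if tok.kind == "name":
            if self.at_op("("):
                if tok.text not in FUNCTIONS:
                    raise ExpressionError(f"unknown function {tok.text!r}", self.text, tok.pos)
                self.next()
                args = [self.parse_or()]
                while self.at_op(","):
                    self.next()
                    args.append(self.parse_or())
                self.expect(")")
                arity = FUNCTIONS[tok.text][0]
                if len(args) != arity:
                    raise ExpressionError(
                        f"{tok.text} expects {arity} argument(s), got {len(args)}",
                        self.text,
                        tok.pos,
                    )
                return Call(tok.text, tuple(args))
            return Sym(tok.text)
        if tok.kind == "op" and tok.text == "(":
            node = self.parse_or()
            self.expect(")")
            return node
        raise ExpressionError(f"unexpected token {tok.text!r}", self.text, tok.pos)


def parse_expression(text: str) -> ExpressionTree:
    """Parse ``text`` into an :class:`ExpressionTree`.

    XML entity escapes (``&gt;`` etc.) must already have been decoded by
    the XML reader; this function sees the plain operators.
    """
    if not text or not text.strip():
        raise ExpressionError("empty expression", text, 0)
    return ExpressionTree(root=_Parser(text).parse(), source_text=text)


# ---------------------------------------------------------------------------
# Queries and evaluation


def _walk(node: Node) -> Iterator[Node]:
    yield node
    if isinstance(node, Unary):
        yield from _walk(node.operand)
    elif isinstance(node, Binary):
        yield from _walk(node.left)
        yield from _walk(node.right)
    elif isinstance(node, Call):
        for a in node.args:
            yield from _walk(a)


def free_symbols(expr: ExpressionTree | Node) -> set[str]:
    """Exact set of identifiers appearing as leaves of the expression."""
    root = expr.root if isinstance(expr, ExpressionTree) else expr
    return {n.name for n in _walk(root) if isinstance(n, Sym)}


def has_boolean_ops(expr: ExpressionTree | Node) -> bool:
    """True if the expression uses comparisons or boolean connectives."""
    root = expr.root if isinstance(expr, ExpressionTree) else expr
    for n in _walk(root):
        if isinstance(n, Binary) and (n.op in _COMPARISONS or n.op in _BOOLEAN_OPS):
            return True
        if isinstance(n, Unary) and n.op == "!":
            return True
    return False


def _eval(node: Node, env: dict):
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Sym):
        try:
            return env[node.name]
        except KeyError:
            raise EvaluationError(f"unbound symbol {node.name!r}") from None
    if isinstance(node, Unary):
        v = _eval(node.operand, env)
        if node.op == "-":
            return -v
        return np.logical_not(v)
    if isinstance(node, Binary):
        a = _eval(node.left, env)
        if node.op == "&&":
            return np.logical_and(a, _eval(node.right, env))
        if node.op == "||":
            return np.logical_or(a, _eval(node.right, env))
        b = _eval(node.right, env)
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        if node.op == "*":
            return a * b
        if node.op == "/":
            if np.isscalar(b) and b == 0:
                raise EvaluationError(f"division by zero in {Binary(node.op, node.left, node.right)}")
            with np.errstate(divide="ignore", invalid="ignore"):
                return a / b
        if node.op == ">":
            return a > b
        if node.op == "<":
            return a < b
        if node.op == ">=":
            return a >= b
        if node.op == "<=":
            return a <= b
        if node.op == "==":
            return a == b
        if node.op == "!=":
            return a != b
        raise AssertionError(node.op)
    if isinstance(node, Call):
        args = [_eval(a, env) for a in node.args]
        if node.func in ("log", "ln"):
            a = args[0]
            bad = a <= 0 if np.isscalar(a) else bool(np.any(np.asarray(a) <= 0))
            if bad:
                raise EvaluationError(f"log of non-positive value in {node}")
        if node.func == "sqrt":
            a = args[0]
            bad = a < 0 if np.isscalar(a) else bool(np.any(np.asarray(a) < 0))
            if bad:
                raise EvaluationError(f"sqrt of negative value in {node}")
        return FUNCTIONS[node.func][1](*args)
    raise AssertionError(f"unknown node {node!r}")


def evaluate(expr: ExpressionTree | Node, env: dict):
    """Evaluate against ``env`` (symbol name -> scalar or numpy array).

    Arithmetic is IEEE double precision; comparisons and boolean operators
    yield booleans (elementwise for array inputs).  Every free symbol must
    be bound, otherwise :class:`EvaluationError` is raised.
    """
    root = expr.root if isinstance(expr, ExpressionTree) else expr
    out = _eval(root, env)
    if isinstance(out, float) and (math.isinf(out) or math.isnan(out)):
        src = expr.source_text if isinstance(expr, ExpressionTree) else str(expr)
        raise EvaluationError(f"non-finite result evaluating {src!r}")
    return out


def serialize(expr: ExpressionTree | Node) -> str:
    """Render an expression as text that re-parses to an identical tree.

    Output is fully parenthesised, so precedence is preserved trivially.
    """
    root = expr.root if isinstance(expr, ExpressionTree) else expr
    return str(root)


def structurally_equal(a: ExpressionTree | Node, b: ExpressionTree | Node) -> bool:
    ra = a.root if isinstance(a, ExpressionTree) else a
    rb = b.root if isinstance(b, ExpressionTree) else b
    return ra == rb
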