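"""Expression language used for every user-supplied formula.

Diffusivities, kinetics, boundary data, domain indicators, initial conditions
and view expressions are all plain text in a small calculator grammar:

.. code-block:: none

    expr    := term (("+" | "-") term)*
    term    := factor (("*" | "/") factor)*
    factor  := "-" factor | power
    power   := atom ("^" factor)?          # right-associative, binds above unary minus
    atom    := NUMBER | SYMBOL | FUNC "(" expr ("," expr)* ")" | "(" expr ")"

Symbols are case-sensitive identifiers (species names, ``x``, ``y``, ``t``,
parameters, the constant ``pi``).  Spatial-derivative tokens are written with
an underscore suffix on a species name: ``u_x``, ``u_y`` (central first
differences), ``u_xx``, ``u_yy`` (second differences) and the explicitly
one-sided ``u_x_b``/``u_x_f``/``u_y_b``/``u_y_f`` upwind variants.  Mixed
derivatives do not exist in the token set.  ``I_S(x, y)`` and ``I_T(x, y)``
sample uploaded images as spatial functions.

Evaluation is pure and elementwise over grid-shaped numpy arrays; division by
zero or ``log`` of a non-positive value produces ``inf``/``nan`` rather than
raising, so that blow-up detection downstream owns the user-facing error.
``heaviside(0)`` evaluates to 1.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Expr",
    "ExprError",
    "parse",
    "evaluate",
    "DERIVATIVE_SUFFIXES",
    "derivative_token",
    "FUNCTIONS",
    "IMAGE_FUNCTIONS",
]


class ExprError(ValueError):
    """Syntax or symbol-resolution error, carrying the source position."""

    def __init__(self, message: str, src: str, pos: int):
        self.src = src
        self.pos = pos
        super().__init__(f"{message} (at position {pos} in {src!r})")


def _nary(op):
    def apply(*args):
        return functools.reduce(op, args)

    return apply


# name -> (callable, min_arity, max_arity); None = unbounded
FUNCTIONS = {
    "sin": (np.sin, 1, 1),
    "cos": (np.cos, 1, 1),
    "tan": (np.tan, 1, 1),
    "exp": (np.exp, 1, 1),
    "log": (np.log, 1, 1),
    "sqrt": (np.sqrt, 1, 1),
    "abs": (np.abs, 1, 1),
    "tanh": (np.tanh, 1, 1),
    "min": (_nary(np.minimum), 2, None),
    "max": (_nary(np.maximum), 2, None),
    # convention: heaviside(0) = 1
    "heaviside": (lambda a: np.where(np.asarray(a) >= 0, 1.0, 0.0), 1, 1),
}

IMAGE_FUNCTIONS = ("I_S", "I_T")

CONSTANTS = {"pi": np.pi}

# suffixes recognised as derivative tokens on a species name
DERIVATIVE_SUFFIXES = ("x", "y", "xx", "yy", "x_b", "x_f", "y_b", "y_f")
MIXED_SUFFIXES = ("xy", "yx")

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/^(),]))"
)


def derivative_token(name: str, species_names) -> tuple[str, str] | None:
    """Split ``name`` into (species, suffix) if it is a derivative token.

    The species list disambiguates names that themselves contain
    underscores (e.g. a species called ``a_1``).
    """
    for sp in species_names:
        prefix = sp + "_"
        if name.startswith(prefix):
            suffix = name[len(prefix):]
            if suffix in DERIVATIVE_SUFFIXES or suffix in MIXED_SUFFIXES:
                return sp, suffix
    return None


@dataclass(frozen=True)
class Expr:
    """Parsed expression: source text, AST and resolved free symbols."""

    src: str
    ast: tuple = field(compare=False)
    free_symbols: frozenset = field(compare=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Expr({self.src!r})"


def _tokenize(src: str):
    tokens = []
    pos = 0
    n = len(src)
    while pos < n:
        m = _TOKEN_RE.match(src, pos)
        if m is None:
            # nothing matched: either trailing whitespace or a bad char
            rest = src[pos:]
            if rest.strip() == "":
                break
            bad = pos + len(rest) - len(rest.lstrip())
            raise ExprError(f"unexpected character {src[bad]!r}", src, bad)
        if m.group("num") is not None:
            tokens.append(("num", float(m.group("num")), m.start("num")))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name"), m.start("name")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    tokens.append(("end", None, n))
    return tokens


class _Parser:
    def __init__(self, src: str, tokens):
        self.src = src
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op):
        kind, val, pos = self.peek()
        if kind == "op" and val == op:
            return self.next()
        raise ExprError(f"expected {op!r}", self.src, pos)

    def parse_expr(self):
        node = self.parse_term()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "+-":
                self.next()
                node = ("bin", val, node, self.parse_term())
            else:
                return node

    def parse_term(self):
        node = self.parse_factor()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "*/":
                self.next()
                node = ("bin", val, node, self.parse_factor())
            else:
                return node

    def parse_factor(self):
        kind, val, _ = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return ("neg", self.parse_factor())
        if kind == "op" and val == "+":
            self.next()
            return self.parse_factor()
        return self.parse_power()

    def parse_power(self):
        base = self.parse_atom()
        kind, val, _ = self.peek()
        if kind == "op" and val == "^":
            self.next()
            # right-associative; exponent may carry a unary minus
            return ("bin", "^", base, self.parse_factor())
        return base

    def parse_atom(self):
        kind, val, pos = self.next()
        if kind == "num":
            return ("num", val)
        if kind == "name":
            nkind, nval, _ = self.peek()
            if nkind == "op" and nval == "(":
                self.next()
                args = [self.parse_expr()]
                while True:
                    k2, v2, p2 = self.peek()
                    if k2 == "op" and v2 == ",":
                        self.next()
                        args.append(self.parse_expr())
                    elif k2 == "op" and v2 == ")":
                        self.next()
                        break
                    else:
                        raise ExprError("expected ',' or ')'", self.src, p2)
                return ("call", val, tuple(args), pos)
            return ("sym", val, pos)
        if kind == "op" and val == "(":
            node = self.parse_expr()
            self.expect_op(")")
            return node
        raise ExprError("expected a value", self.src, pos)


def _check_symbols(ast, src, allowed, found):
    kind = ast[0]
    if kind == "sym":
        _, name, pos = ast
        if name in CONSTANTS:
            return
        if name not in allowed:
            raise ExprError(f"unknown symbol {name!r}", src, pos)
        found.add(name)
    elif kind == "call":
        _, name, args, pos = ast
        if name in FUNCTIONS:
            fn, lo, hi = FUNCTIONS[name]
            if len(args) < lo or (hi is not None and len(args) > hi):
                raise ExprError(
                    f"{name}() takes "
                    + (f"{lo}" if hi == lo else f"at least {lo}")
                    + f" argument(s), got {len(args)}",
                    src,
                    pos,
                )
        elif name in IMAGE_FUNCTIONS:
            if name not in allowed:
                raise ExprError(f"image function {name!r} not available here", src, pos)
            if len(args) != 2:
                raise ExprError(f"{name}(x, y) takes 2 arguments", src, pos)
            found.add(name)
        else:
            raise ExprError(f"unknown function {name!r}", src, pos)
        for a in args:
            _check_symbols(a, src, allowed, found)
    elif kind == "bin":
        _check_symbols(ast[2], src, allowed, found)
        _check_symbols(ast[3], src, allowed, found)
    elif kind == "neg":
        _check_symbols(ast[1], src, allowed, found)


def parse(src: str, allowed_symbols) -> Expr:
    """Parse ``src`` into an :class:`Expr`.

    ``allowed_symbols`` is the complete set of names that may appear free
    (species, coordinates, ``t``, parameters, derivative tokens, image
    function names).  ``pi`` is always available.  Raises :class:`ExprError`
    with a source position on a syntax error or an unknown symbol.
    """
    if not isinstance(src, str) or src.strip() == "":
        raise ExprError("empty expression", src if isinstance(src, str) else "", 0)
    tokens = _tokenize(src)
    parser = _Parser(src, tokens)
    ast = parser.parse_expr()
    kind, _, pos = parser.peek()
    if kind != "end":
        raise ExprError("unexpected trailing input", src, pos)
    found: set[str] = set()
    _check_symbols(ast, src, set(allowed_symbols), found)
    return Expr(src=src, ast=ast, free_symbols=frozenset(found))


def _eval(ast, ctx):
    kind = ast[0]
    if kind == "num":
        return ast[1]
    if kind == "sym":
        name = ast[1]
        if name in CONSTANTS:
            return CONSTANTS[name]
        return ctx[name]
    if kind == "neg":
        return -_eval(ast[1], ctx)
    if kind == "bin":
        op = ast[1]
        a = _eval(ast[2], ctx)
        b = _eval(ast[3], ctx)
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return np.true_divide(a, b)
        return np.power(a, b)
    # call
    name, args = ast[1], ast[2]
    vals = [_eval(a, ctx) for a in args]
    if name in FUNCTIONS:
        return FUNCTIONS[name][0](*vals)
    sampler = ctx[name]  # image function
    return sampler(vals[0], vals[1])


def evaluate(e: Expr, ctx):
    """Evaluate ``e`` elementwise against ``ctx`` (a mapping symbol -> value).

    Values may be scalars or grid-shaped arrays; numpy broadcasting applies.
    Non-finite intermediate results flow through silently.
    """
    with np.errstate(all="ignore"):
        return _eval(e.ast, ctx)
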