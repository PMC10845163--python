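"""BoolNet-dialect ``.bnet`` reading, writing and compilation.

The dialect: an optional ``targets, factors`` header; ``#`` comments; one
rule per line, ``name, expression`` with operators ``!`` (NOT), ``&``
(AND), ``|`` (OR), parentheses, and the constants ``0``/``1``.  Node order
follows file order.  Expressions compile to truth tables by exhaustive
evaluation over the node's referenced variables, yielding a
:class:`~cyclesym.network.BooleanFunctionNetwork` with identical dynamics.

``threshold_to_bnet`` goes the other way for signed threshold networks: a
node's rule becomes the disjunction of minterms over its regulators whose
signed input sum is strictly positive (constant 0 when no pattern
activates), so the compiled model reproduces the threshold dynamics bit
for bit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .network import BooleanFunctionNetwork, SignedNetwork

__all__ = [
    "BnetParseError",
    "BnetModel",
    "parse_bnet",
    "read_bnet",
    "write_bnet",
    "compile_model",
    "threshold_to_bnet",
]

MAX_INPUTS = 16

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")
_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.]*)"
                       r"|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


class BnetParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


# ---- expression AST ------------------------------------------------------

@dataclass(frozen=True)
class _Var:
    name: str

    def eval(self, env):
        return env[self.name]

    def vars(self, acc):
        acc.add(self.name)

    def unparse(self):
        return self.name


@dataclass(frozen=True)
class _Const:
    value: int

    def eval(self, env):
        return self.value

    def vars(self, acc):
        pass

    def unparse(self):
        return str(self.value)


@dataclass(frozen=True)
class _Not:
    arg: object

    def eval(self, env):
        return 1 - self.arg.eval(env)

    def vars(self, acc):
        self.arg.vars(acc)

    def unparse(self):
        inner = self.arg.unparse()
        if isinstance(self.arg, (_Var, _Const, _Not)):
            return f"!{inner}"
        return f"!({inner})"


@dataclass(frozen=True)
class _BinOp:
    op: str                     # "&" or "|"
    args: tuple

    def eval(self, env):
        vals = [a.eval(env) for a in self.args]
        return max(vals) if self.op == "|" else min(vals)

    def vars(self, acc):
        for a in self.args:
            a.vars(acc)

    def unparse(self):
        parts = []
        for a in self.args:
            s = a.unparse()
            if isinstance(a, _BinOp) and (self.op == "&" and a.op == "|"):
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


def _tokenize(text: str, line: int):
    pos, tokens = 0, []
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise BnetParseError(f"unexpected character {text[pos]!r}", line)
        if m.group("name"):
            tokens.append(("name", m.group("name")))
        elif m.group("const"):
            tokens.append(("const", int(m.group("const"))))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser: or := and ('|' and)*, and := unary ('&' unary)*,
    unary := '!' unary | name | 0 | 1 | '(' or ')'."""

    def __init__(self, tokens, line):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise BnetParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self):
        expr = self.parse_or()
        if self.peek() is not None:
            raise BnetParseError(
                f"trailing tokens after expression: {self.peek()[1]!r}", self.line)
        return expr

    def parse_or(self):
        parts = [self.parse_and()]
        while self.peek() == ("op", "|"):
            self.take()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else _BinOp("|", tuple(parts))

    def parse_and(self):
        parts = [self.parse_unary()]
        while self.peek() == ("op", "&"):
            self.take()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else _BinOp("&", tuple(parts))

    def parse_unary(self):
        tok = self.take()
        if tok == ("op", "!"):
            return _Not(self.parse_unary())
        if tok == ("op", "("):
            expr = self.parse_or()
            if self.take() != ("op", ")"):
                raise BnetParseError("missing closing parenthesis", self.line)
            return expr
        kind, val = tok
        if kind == "name":
            return _Var(val)
        if kind == "const":
            return _Const(val)
        raise BnetParseError(f"unexpected token {val!r}", self.line)


@dataclass(frozen=True)
class BnetModel:
    """Parsed Boolean model: node names in file order plus one expression AST
    per node."""

    names: tuple
    exprs: tuple

    @property
    def n(self) -> int:
        return len(self.names)

    def expression_str(self, i: int) -> str:
        return self.exprs[i].unparse()


def parse_bnet(text: str) -> BnetModel:
    names: list[str] = []
    exprs: list = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise BnetParseError("expected 'name, expression'", lineno)
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if target.lower() == "targets" and expr_text.strip().lower() == "factors":
            continue  # header
        if not _NAME_RE.fullmatch(target):
            raise BnetParseError(f"invalid node name {target!r}", lineno)
        if target in names:
            raise BnetParseError(f"duplicate target {target!r}", lineno)
        tokens = _tokenize(expr_text, lineno)
        if not tokens:
            raise BnetParseError("empty expression", lineno)
        expr = _Parser(tokens, lineno).parse()
        names.append(target)
        exprs.append(expr)
    if not names:
        raise BnetParseError("no rules found")
    declared = set(names)
    for name, expr in zip(names, exprs):
        used: set = set()
        expr.vars(used)
        missing = used - declared
        if missing:
            raise BnetParseError(
                f"rule for {name!r} references undeclared node(s) "
                f"{sorted(missing)}")
    return BnetModel(names=tuple(names), exprs=tuple(exprs))


def read_bnet(path) -> BnetModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_bnet(fh.read())


def write_bnet(model: BnetModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("targets, factors\n")
        for name, expr in zip(model.names, model.exprs):
            fh.write(f"{name}, {expr.unparse()}\n")


def compile_model(model: BnetModel) -> BooleanFunctionNetwork:
    """Enumerate each rule's truth table over its referenced variables.

    Inputs follow declaration (file) order; a node whose rule is constant
    gets a zero-input, single-entry table.
    """
    index = {name: i for i, name in enumerate(model.names)}
    inputs, tables = [], []
    for name, expr in zip(model.names, model.exprs):
        used: set = set()
        expr.vars(used)
        inp = tuple(index[v] for v in model.names if v in used)
        k = len(inp)
        if k > MAX_INPUTS:
            raise ValueError(
                f"node {name!r} has {k} inputs; compilation capped at "
                f"{MAX_INPUTS}")
        table = np.empty(1 << k, dtype=np.uint8)
        for pattern in range(1 << k):
            env = {model.names[src]: (pattern >> j) & 1
                   for j, src in enumerate(inp)}
            table[pattern] = expr.eval(env)
        inputs.append(inp)
        tables.append(table)
    return BooleanFunctionNetwork(n=model.n, inputs=tuple(inputs),
                                  tables=tuple(tables), names=model.names)


def threshold_to_bnet(net: SignedNetwork, names=None) -> BnetModel:
    """Express the strict-positive-sum threshold rule as explicit Boolean
    expressions, one minterm per activating regulator pattern."""
    n = net.n
    if names is None:
        names = tuple(f"v{i}" for i in range(n))
    exprs = []
    for i in range(n):
        regs = [j for j in range(n) if net.W[j, i] != 0]
        k = len(regs)
        if k > MAX_INPUTS:
            raise ValueError(
                f"node {i} has in-degree {k}; conversion capped at {MAX_INPUTS}")
        minterms = []
        for pattern in range(1 << k):
            total = sum(int(net.W[j, i]) for b, j in enumerate(regs)
                        if (pattern >> b) & 1)
            if total > 0:
                lits = [_Var(names[j]) if (pattern >> b) & 1
                        else _Not(_Var(names[j]))
                        for b, j in enumerate(regs)]
                minterms.append(lits[0] if len(lits) == 1
                                else _BinOp("&", tuple(lits)))
        if not minterms:
            exprs.append(_Const(0))
        elif len(minterms) == 1:
            exprs.append(minterms[0])
        else:
            exprs.append(_BinOp("|", tuple(minterms)))
    return BnetModel(names=tuple(names), exprs=tuple(exprs))
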