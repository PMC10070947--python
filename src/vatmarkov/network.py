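"""Boolean gene-regulatory networks in the BoolNet "targets, factors" dialect.

A :class:`BooleanNetwork` holds named nodes, one Boolean update rule per node,
and a designated subset of *input* nodes (environmental signals such as
cytokines, insulin, TLR4 ligands or extracellular ceramide).  Dynamics are
synchronous: at every time step all rules are evaluated on the current state
simultaneously.  Environmental conditions are imposed with a
:class:`Clamping`, which overrides the rule of the clamped nodes at every
step; a clamped node is an experimenter-imposed boundary condition, not an
intracellular variable, so it is also exempt from noise (see
:mod:`vatmarkov.markov`).

Rule files look like::

    targets, factors
    # a toggle switch
    A, ! B
    B, ! A

with operators ``!``/``NOT``, ``&``/``AND``, ``|``/``OR``, parentheses and the
constants ``0``/``1``.  A node whose rule is exactly itself (``X, X``) is
constant under free dynamics and is auto-declared an input node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BooleanNetwork",
    "Clamping",
    "NetworkParseError",
    "parse_network",
    "serialize_network",
    "step",
]


class NetworkParseError(ValueError):
    """Raised when a rule file violates the dialect (with line information)."""


# --------------------------------------------------------------------------
# Boolean expression AST
# --------------------------------------------------------------------------

class Expr:
    """Node of a Boolean expression tree.

    ``eval`` accepts an environment mapping node names to values supporting
    ``&``, ``|`` and ``^`` (python bools, ``numpy.bool_`` scalars or boolean
    arrays), so one expression tree serves both scalar stepping and the
    vectorized whole-state-space evaluation used by the attractor machinery.
    """

    def eval(self, env):  # pragma: no cover - abstract
        raise NotImplementedError

    def names(self) -> set[str]:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: bool

    def eval(self, env):
        return self.value

    def names(self):
        return set()

    def __str__(self):
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def eval(self, env):
        return env[self.name]

    def names(self):
        return {self.name}

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def eval(self, env):
        return self.operand.eval(env) ^ True

    def names(self):
        return self.operand.names()

    def __str__(self):
        return f"! {self.operand}" if isinstance(self.operand, (Var, Const)) else f"! ({self.operand})"


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr

    def eval(self, env):
        return self.left.eval(env) & self.right.eval(env)

    def names(self):
        return self.left.names() | self.right.names()

    def __str__(self):
        return f"{self._wrap(self.left)} & {self._wrap(self.right)}"

    @staticmethod
    def _wrap(e: Expr) -> str:
        return f"({e})" if isinstance(e, Or) else str(e)


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr

    def eval(self, env):
        return self.left.eval(env) | self.right.eval(env)

    def names(self):
        return self.left.names() | self.right.names()

    def __str__(self):
        return f"{self.left} | {self.right}"


_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<not>!)|(?P<and>&+)"
                       r"|(?P<or>\|+)|(?P<name>[\w.\-]+))")

_WORD_OPS = {"NOT": "not", "AND": "and", "OR": "or"}


def _tokenize(text: str, line_no: int | None = None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise NetworkParseError(
                f"unexpected character {rest[0]!r} in expression"
                + (f" (line {line_no})" if line_no else ""))
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "name":
            upper = value.upper()
            if upper in _WORD_OPS:
                kind = _WORD_OPS[upper]
        tokens.append((kind, value))
    return tokens


class _Parser:
    """Recursive-descent parser; precedence NOT > AND > OR."""

    def __init__(self, tokens: list[tuple[str, str]], line_no: int | None = None):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def _err(self, msg: str) -> NetworkParseError:
        loc = f" (line {self.line_no})" if self.line_no else ""
        return NetworkParseError(msg + loc)

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        if not self.tokens:
            raise self._err("empty expression")
        e = self.parse_or()
        if self.pos != len(self.tokens):
            raise self._err(f"trailing input near {self.peek()[1]!r}")
        return e

    def parse_or(self) -> Expr:
        e = self.parse_and()
        while self.peek()[0] == "or":
            self.take()
            e = Or(e, self.parse_and())
        return e

    def parse_and(self) -> Expr:
        e = self.parse_factor()
        while self.peek()[0] == "and":
            self.take()
            e = And(e, self.parse_factor())
        return e

    def parse_factor(self) -> Expr:
        kind, value = self.take()
        if kind == "not":
            return Not(self.parse_factor())
        if kind == "lpar":
            e = self.parse_or()
            if self.take()[0] != "rpar":
                raise self._err("missing closing parenthesis")
            return e
        if kind == "name":
            if value == "0":
                return Const(False)
            if value == "1":
                return Const(True)
            return Var(value)
        raise self._err(f"unexpected token {value!r}")


def parse_expression(text: str, line_no: int | None = None) -> Expr:
    """Parse a single Boolean expression (used by rule files and tests)."""
    return _Parser(_tokenize(text, line_no), line_no).parse()


# --------------------------------------------------------------------------
# Network, clamping, stepping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A named Boolean network with a fixed, declaration-order node list.

    Node order is deliberately the declaration order of the rule file (never
    alphabetical) so that printed state vectors and attractor tables are
    stable and reproducible.
    """

    name: str
    nodes: tuple[str, ...]
    rules: Mapping[str, Expr]
    inputs: tuple[str, ...] = ()
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        missing = [n for n in self.nodes if n not in self.rules]
        if missing:
            raise ValueError(f"nodes without rules: {missing}")
        undeclared = sorted(
            set().union(*(r.names() for r in self.rules.values())) - set(self.nodes))
        if undeclared:
            raise ValueError(f"rules reference undeclared nodes: {undeclared}")
        bad_inputs = [n for n in self.inputs if n not in self.nodes]
        if bad_inputs:
            raise ValueError(f"declared inputs are not nodes: {bad_inputs}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def to_text(self) -> str:
        return serialize_network(self)


class Clamping(dict):
    """Mapping node-name -> 0/1 overriding those nodes' rules at every step."""

    def __init__(self, assignments: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        for k, v in dict(assignments).items():
            if v not in (0, 1, True, False):
                raise ValueError(f"clamp value for {k!r} must be 0 or 1, got {v!r}")
            self[k] = int(v)

    def validate(self, net: BooleanNetwork) -> "Clamping":
        unknown = sorted(set(self) - set(net.nodes))
        if unknown:
            raise KeyError(f"clamped nodes not in network {net.name!r}: {unknown}")
        return self


def parse_network(text: str, name: str = "network",
                  inputs: Sequence[str] | None = None) -> BooleanNetwork:
    """Parse rule-file content in the "targets, factors" dialect.

    A node with the self-rule ``X, X`` is constant under free dynamics and is
    auto-declared an input unless an explicit ``inputs`` list is given.
    Metadata may be carried in ``#!key: value`` comment lines.
    """
    nodes: list[str] = []
    rules: dict[str, Expr] = {}
    rule_lines: dict[str, int] = {}
    metadata: dict[str, str] = {}
    header_seen = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if line.startswith("#!") and ":" in line:
            key, _, value = line[2:].partition(":")
            metadata[key.strip()] = value.strip()
            continue
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            head = [p.strip().lower() for p in line.split(",")]
            if head != ["targets", "factors"]:
                raise NetworkParseError(
                    f'expected header "targets, factors", got {line!r} (line {line_no})')
            header_seen = True
            continue
        if "," not in line:
            raise NetworkParseError(f"malformed rule line {line!r} (line {line_no})")
        target, _, factors = line.partition(",")
        target = target.strip()
        if not re.fullmatch(r"[\w.\-]+", target):
            raise NetworkParseError(f"invalid node name {target!r} (line {line_no})")
        if target in rules:
            raise NetworkParseError(f"duplicate definition of node {target!r} (line {line_no})")
        nodes.append(target)
        rules[target] = parse_expression(factors, line_no)
        rule_lines[target] = line_no
    if not header_seen:
        raise NetworkParseError("empty rule file")
    if not nodes:
        raise NetworkParseError("rule file declares no nodes")

    declared = set(nodes)
    for target in nodes:
        for sym in sorted(rules[target].names() - declared):
            raise NetworkParseError(
                f"rule for {target!r} references undeclared symbol {sym!r} "
                f"(line {rule_lines[target]})")

    if inputs is None:
        inputs = tuple(n for n in nodes if rules[n] == Var(n))
    return BooleanNetwork(name=name, nodes=tuple(nodes), rules=rules,
                          inputs=tuple(inputs), metadata=metadata)


def serialize_network(net: BooleanNetwork) -> str:
    """Render a network back to the rule-file dialect (whitespace-normalized)."""
    lines = [f"#!name: {net.name}"]
    for key, value in net.metadata.items():
        if key != "name":
            lines.append(f"#!{key}: {value}")
    lines.append("targets, factors")
    lines.extend(f"{n}, {net.rules[n]}" for n in net.nodes)
    return "\n".join(lines) + "\n"


def load_network(path, name: str | None = None) -> BooleanNetwork:
    """Read a rule file from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    net = parse_network(text, name=name or "network")
    if name is None and "name" in net.metadata:
        net = BooleanNetwork(net.metadata["name"], net.nodes, net.rules,
                             net.inputs, net.metadata)
    return net


def step(net: BooleanNetwork, state: Sequence[int],
         clamp: Mapping[str, int] | None = None) -> tuple[int, ...]:
    """One synchronous update; clamped nodes take their clamped value."""
    if len(state) != net.n_nodes:
        raise ValueError(f"state length {len(state)} != {net.n_nodes} nodes")
    clamp = clamp or {}
    if clamp:
        Clamping(clamp).validate(net)
    env = {n: bool(v) for n, v in zip(net.nodes, state)}
    out = []
    for n in net.nodes:
        if n in clamp:
            out.append(int(clamp[n]))
        else:
            out.append(int(net.rules[n].eval(env)))
    return tuple(out)
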