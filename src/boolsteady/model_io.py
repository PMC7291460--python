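"""Boolean network definitions and BoolNet-format input/output.

A Boolean network is an ordered list of nodes ``V = {v_1, ..., v_n}`` with one
logical update rule ``f_i`` per node, built from NOT/AND/OR, parentheses, node
names and the constants ``0``/``1``.  States of the network are binary vectors
of length *n*; the first node in the file is the most significant bit, and the
2^n states carry 1-based decimal indices ``S_1 = [00...0]`` through
``S_{2^n} = [11...1]``.

The on-disk format is BoolNet text: a ``targets, factors`` header followed by
one ``name, expression`` line per node.  ``!`` and ``~`` are both accepted for
NOT, ``&`` for AND, ``|`` for OR; comment lines start with ``#``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoolNetSyntaxError",
    "BooleanNetwork",
    "State",
    "parse_boolnet",
    "parse_expression",
    "write_boolnet",
    "evaluate_rule",
    "rule_truth_table",
    "MAX_NODES_DEFAULT",
]

#: Hard cap on network size; 2^n states must remain storable as a sparse STG.
MAX_NODES_DEFAULT = 25


class BoolNetSyntaxError(ValueError):
    """Malformed BoolNet document or logic expression (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

class Expr:
    """Node of a logical expression tree."""

    def evaluate(self, values: dict[str, int | np.ndarray]):
        raise NotImplementedError

    def literals(self) -> set[str]:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, values):
        return values[self.name]

    def literals(self):
        return {self.name}

    def unparse(self):
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def evaluate(self, values):
        return self.value

    def literals(self):
        return set()

    def unparse(self):
        return str(self.value)


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def evaluate(self, values):
        return 1 - self.child.evaluate(values)

    def literals(self):
        return self.child.literals()

    def unparse(self):
        return f"(!{self.child.unparse()})"


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr

    def evaluate(self, values):
        return self.left.evaluate(values) & self.right.evaluate(values)

    def literals(self):
        return self.left.literals() | self.right.literals()

    def unparse(self):
        return f"({self.left.unparse()} & {self.right.unparse()})"


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr

    def evaluate(self, values):
        return self.left.evaluate(values) | self.right.evaluate(values)

    def literals(self):
        return self.left.literals() | self.right.literals()

    def unparse(self):
        return f"({self.left.unparse()} | {self.right.unparse()})"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<not>[!~])|(?P<and>&+)|(?P<or>\|+)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_.]*)|(?P<const>[01])(?![A-Za-z0-9_.]))"
)


def _tokenize(text: str, line: int | None) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise BoolNetSyntaxError(
                f"unexpected character {text[pos:].strip()[0]!r} in expression", line
            )
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


class _Parser:
    """Recursive-descent parser with precedence NOT > AND > OR."""

    def __init__(self, tokens: list[tuple[str, str]], line: int | None):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.pos != len(self.tokens):
            raise BoolNetSyntaxError("trailing tokens after expression", self.line)
        return expr

    def parse_or(self) -> Expr:
        expr = self.parse_and()
        while self.peek() == "or":
            self.take()
            expr = Or(expr, self.parse_and())
        return expr

    def parse_and(self) -> Expr:
        expr = self.parse_unary()
        while self.peek() == "and":
            self.take()
            expr = And(expr, self.parse_unary())
        return expr

    def parse_unary(self) -> Expr:
        kind = self.peek()
        if kind is None:
            raise BoolNetSyntaxError("unexpected end of expression", self.line)
        if kind == "not":
            self.take()
            return Not(self.parse_unary())
        if kind == "lpar":
            self.take()
            expr = self.parse_or()
            if self.peek() != "rpar":
                raise BoolNetSyntaxError("unbalanced parenthesis", self.line)
            self.take()
            return expr
        if kind == "name":
            return Var(self.take()[1])
        if kind == "const":
            return Const(int(self.take()[1]))
        raise BoolNetSyntaxError(f"unexpected token {self.tokens[self.pos][1]!r}", self.line)


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a single logic expression (NOT/AND/OR, parens, names, 0/1)."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise BoolNetSyntaxError("empty expression", line)
    return _Parser(tokens, line).parse()


# ---------------------------------------------------------------------------
# BooleanNetwork and State
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """Ordered nodes plus one update rule per node.

    ``nodes[0]`` is the most significant bit of the state index; rules may
    reference any declared node or the constants 0/1.
    """

    nodes: list[str]
    rules: list[Expr]
    max_nodes: int = MAX_NODES_DEFAULT
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.nodes) != len(self.rules):
            raise ValueError("one rule required per node")
        if len(self.nodes) < 1:
            raise ValueError("network needs at least one node")
        if len(self.nodes) > self.max_nodes:
            raise ValueError(
                f"network has {len(self.nodes)} nodes, above the size cap of "
                f"{self.max_nodes} (2^n states must stay tractable)"
            )
        seen = set()
        for name in self.nodes:
            if not name or re.search(r"[\s,]", name):
                raise ValueError(f"invalid node name {name!r}")
            if name in seen:
                raise ValueError(f"duplicate node {name!r}")
            seen.add(name)
        for name, rule in zip(self.nodes, self.rules):
            undeclared = rule.literals() - seen
            if undeclared:
                raise ValueError(
                    f"rule for {name!r} references undeclared node(s) "
                    f"{sorted(undeclared)}"
                )
        self._index = {name: j for j, name in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_states(self) -> int:
        return 2 ** self.n

    def node_index(self, name: str) -> int:
        """0-based position of a node name."""
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    # -- state indexing (node 1 = most significant bit, indices 1-based) ----

    def state_bits(self, index: int) -> np.ndarray:
        """Bits of state ``S_index`` (1-based decimal index)."""
        if not 1 <= index <= self.n_states:
            raise IndexError(f"state index {index} outside 1..{self.n_states}")
        s = index - 1
        return np.array([(s >> (self.n - 1 - j)) & 1 for j in range(self.n)], dtype=np.int8)

    def state_index(self, bits) -> int:
        """1-based decimal index of a bit vector."""
        bits = np.asarray(bits, dtype=int)
        if bits.shape != (self.n,) or not np.isin(bits, (0, 1)).all():
            raise ValueError("state must be a 0/1 vector of length n")
        s = 0
        for b in bits:
            s = (s << 1) | int(b)
        return s + 1

    def state_label(self, index: int) -> str:
        """Bit-string label such as '110' for S_7 of a 3-node model."""
        return "".join(str(b) for b in self.state_bits(index))

    def all_states(self) -> np.ndarray:
        """(2^n, n) array of all state bit vectors in index order."""
        s = np.arange(self.n_states, dtype=np.int64)
        cols = [(s >> (self.n - 1 - j)) & 1 for j in range(self.n)]
        return np.stack(cols, axis=1).astype(np.int8)


@dataclass(frozen=True)
class State:
    """A single network state: bit vector plus its 1-based decimal index."""

    bits: tuple[int, ...]
    index: int

    @classmethod
    def from_bits(cls, net: BooleanNetwork, bits) -> "State":
        return cls(tuple(int(b) for b in bits), net.state_index(bits))

    @classmethod
    def from_index(cls, net: BooleanNetwork, index: int) -> "State":
        return cls(tuple(int(b) for b in net.state_bits(index)), index)


# ---------------------------------------------------------------------------
# Parsing / writing documents
# ---------------------------------------------------------------------------

def parse_boolnet(text: str, max_nodes: int = MAX_NODES_DEFAULT) -> BooleanNetwork:
    """Parse a BoolNet document into a :class:`BooleanNetwork`.

    The node order is the file order.  Raises :class:`BoolNetSyntaxError` with
    a line number on malformed input, and ``ValueError`` for undeclared
    literals or duplicate nodes.
    """
    nodes: list[str] = []
    exprs: list[Expr] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
                header_seen = True
                continue
            raise BoolNetSyntaxError("expected 'targets, factors' header", lineno)
        if "," not in line:
            raise BoolNetSyntaxError("expected 'name, expression'", lineno)
        name, _, expr_text = line.partition(",")
        name = name.strip()
        if not name:
            raise BoolNetSyntaxError("empty target name", lineno)
        nodes.append(name)
        exprs.append(parse_expression(expr_text, lineno))
    if not header_seen:
        raise BoolNetSyntaxError("missing 'targets, factors' header", 1)
    if not nodes:
        raise BoolNetSyntaxError("no rules found after header", 1)
    return BooleanNetwork(nodes, exprs, max_nodes=max_nodes)


def write_boolnet(net: BooleanNetwork) -> str:
    """Serialize a network back to BoolNet text (unambiguously parenthesized)."""
    lines = ["targets, factors"]
    for name, rule in zip(net.nodes, net.rules):
        lines.append(f"{name}, {rule.unparse()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rule evaluation
# ---------------------------------------------------------------------------

def evaluate_rule(net: BooleanNetwork, node_index: int, state) -> int:
    """Evaluate ``f_{node_index}`` (1-based node index) on one state.

    ``state`` may be a :class:`State`, a bit sequence, or a 1-based decimal
    state index.
    """
    if not 1 <= node_index <= net.n:
        raise IndexError(f"node index {node_index} outside 1..{net.n}")
    if isinstance(state, State):
        bits = np.asarray(state.bits)
    elif isinstance(state, (int, np.integer)):
        bits = net.state_bits(int(state))
    else:
        bits = np.asarray(state, dtype=int)
        if bits.shape != (net.n,):
            raise ValueError("state length does not match network size")
    values = {name: int(bits[j]) for j, name in enumerate(net.nodes)}
    return int(net.rules[node_index - 1].evaluate(values)) & 1


def rule_truth_table(net: BooleanNetwork, node_index: int) -> np.ndarray:
    """Vector of ``f_{node_index}`` over all 2^n states (in index order)."""
    states = net.all_states()
    values = {name: states[:, j].astype(np.int64) for j, name in enumerate(net.nodes)}
    out = net.rules[node_index - 1].evaluate(values)
    return (np.broadcast_to(out, (net.n_states,)) & 1).astype(np.int8)
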