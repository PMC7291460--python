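"""Programmatic model fixtures.

Everything the package needs for testing is generated here: the 3-node worked
example used throughout the docs, a minimal cyclic-attractor model, an
input-node variant whose state space splits into disconnected subgraphs, and
reproducible random networks for property-based checks.  Published biological
models are deliberately not bundled; they can be supplied as external .bnet
files (see :func:`load_external_models`).
"""

from __future__ import annotations

import os

import numpy as np

from .model_io import And, BooleanNetwork, Const, Expr, Not, Or, Var, parse_boolnet

__all__ = ["toy3", "oscillator", "input_split", "random_bn", "load_external_models"]

TOY3_TEXT = """\
targets, factors
A, !B
B, !A & C
C, B | C
"""


def toy3() -> BooleanNetwork:
    """The 3-node example network: F = {¬B, ¬A∧C, B∨C}.

    Its 8-state transition graph is acyclic with three fixed points,
    [011], [100] and [101], and five transient states.
    """
    return parse_boolnet(TOY3_TEXT)


def oscillator() -> BooleanNetwork:
    """2-node relaxation oscillator A* = B, B* = ¬A.

    The entire 4-state STG is a single terminal cycle
    00 → 01 → 11 → 10 → 00, i.e. one cyclic attractor and no transient
    states (u = 0, q = 1).
    """
    return parse_boolnet("targets, factors\nA, B\nB, !A\n")


def input_split() -> BooleanNetwork:
    """The 3-node example plus a non-dynamic input node I (rule I = I).

    No transition can flip I, so the 16-state STG splits into two
    disconnected 8-state subgraphs, one per value of I.
    """
    return parse_boolnet("targets, factors\nA, !B\nB, !A & C\nC, B | C\nI, I\n")


def _random_expr(rng: np.random.Generator, regulators: list[str], depth: int) -> Expr:
    if depth <= 0 or (len(regulators) == 1 and rng.random() < 0.7):
        leaf: Expr = Var(rng.choice(regulators))
        return Not(leaf) if rng.random() < 0.3 else leaf
    op = And if rng.random() < 0.5 else Or
    left = _random_expr(rng, regulators, depth - 1)
    right = _random_expr(rng, regulators, depth - 1)
    expr = op(left, right)
    return Not(expr) if rng.random() < 0.15 else expr


def random_bn(n: int, k: int = 2, seed: int = 0) -> BooleanNetwork:
    """Random Boolean network: each node gets a random NOT/AND/OR expression
    over at most *k* random regulators.  Reproducible under ``seed``."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(1, n + 1)]
    rules: list[Expr] = []
    for _ in nodes:
        in_deg = int(rng.integers(1, min(k, n) + 1))
        regs = list(rng.choice(nodes, size=in_deg, replace=False))
        if rng.random() < 0.02:
            rules.append(Const(int(rng.integers(0, 2))))
        else:
            rules.append(_random_expr(rng, regs, depth=2))
    return BooleanNetwork(nodes, rules)


def load_external_models(directory: str | os.PathLike) -> list[tuple[str, BooleanNetwork]]:
    """Load any user-supplied .bnet models from ``directory``.

    Published biological models are not distributed with the package; drop
    their BoolNet encodings into a directory and pass it here (or to the CLI)
    to run the same analyses on them.  Returns an empty list, without error,
    when the directory is absent or holds no .bnet files.
    """
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        return []
    models = []
    for fname in sorted(os.listdir(directory)):
        if fname.endswith(".bnet"):
            with open(os.path.join(directory, fname)) as fh:
                models.append((fname[:-5], parse_boolnet(fh.read())))
    return models
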