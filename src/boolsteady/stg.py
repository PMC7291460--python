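"""State transition graph construction for asynchronous continuous-time updating.

Under asynchronous updating exactly one node flips per event.  From state
``S_i`` there is an arc to the state differing in node *k* whenever the rule
``f_k`` applied to ``S_i`` disagrees with the current value of node *k*; the
arc carries the activation rate ``u_k`` if the flip is 0→1 and the
deactivation rate ``d_k`` if it is 1→0.

The kinetic matrix *K* is the (column-convention) Laplacian of this graph:
``K[j, i]`` holds the rate of the transition ``S_i → S_j`` and each diagonal
entry is minus the sum of the off-diagonal entries of its column, so columns
sum to zero and ``dx/dt = K x`` conserves total probability.

Only the numeric rate values depend on the parameters; the arc list and the
sparsity pattern are functions of the logic alone and are computed once per
model (see :class:`TransitionTable` and ``build_kinetic_matrix``), which is
the main performance lever for parameter scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model_io import BooleanNetwork, rule_truth_table

__all__ = [
    "TransitionRates",
    "TransitionTable",
    "enumerate_transitions",
    "build_kinetic_matrix",
    "refresh_kinetic_matrix",
    "split_subgraphs",
    "make_initial_condition",
    "validate_probability_vector",
    "parse_rates_text",
    "PROB_ATOL",
]

#: Absolute tolerance on probability-vector normalization and column sums.
PROB_ATOL = 1e-12


# ---------------------------------------------------------------------------
# Transition rates
# ---------------------------------------------------------------------------

@dataclass
class TransitionRates:
    """Per-node activation (``u``) and deactivation (``d``) rates, in 1/time.

    A zero rate encodes a knocked-out transition; negative, non-finite or
    missing rates are rejected.
    """

    u: dict[str, float]
    d: dict[str, float]

    def __post_init__(self):
        for tag, table in (("u", self.u), ("d", self.d)):
            for node, value in table.items():
                value = float(value)
                if not np.isfinite(value) or value < 0:
                    raise ValueError(f"rate {tag}_{node} = {value} must be finite and >= 0")
                table[node] = value

    @classmethod
    def uniform(cls, net: BooleanNetwork, value: float = 1.0) -> "TransitionRates":
        """All rates equal (the common default of 1 per unit time)."""
        return cls({v: value for v in net.nodes}, {v: value for v in net.nodes})

    @classmethod
    def random(cls, net: BooleanNetwork, seed: int, low: float = 0.1,
               high: float = 10.0) -> "TransitionRates":
        """Log-uniform random rates in [low, high], reproducible under seed."""
        rng = np.random.default_rng(seed)
        draw = lambda: float(10 ** rng.uniform(np.log10(low), np.log10(high)))
        return cls({v: draw() for v in net.nodes}, {v: draw() for v in net.nodes})

    def validate_for(self, net: BooleanNetwork) -> None:
        for v in net.nodes:
            if v not in self.u or v not in self.d:
                raise KeyError(f"missing rate for node {v!r}")

    def get(self, name: str) -> float:
        """Look up a rate by its flat name ``u_<node>`` or ``d_<node>``."""
        kind, _, node = name.partition("_")
        table = {"u": self.u, "d": self.d}.get(kind)
        if table is None or node not in table:
            raise KeyError(f"unknown rate parameter {name!r}")
        return table[node]

    def replace(self, **named: float) -> "TransitionRates":
        """Copy with flat-named rates (``u_X=2.0``) replaced."""
        u, d = dict(self.u), dict(self.d)
        for name, value in named.items():
            kind, _, node = name.partition("_")
            table = {"u": u, "d": d}.get(kind)
            if table is None or node not in table:
                raise KeyError(f"unknown rate parameter {name!r}")
            table[node] = float(value)
        return TransitionRates(u, d)

    def flat(self) -> dict[str, float]:
        out = {f"u_{v}": r for v, r in self.u.items()}
        out.update({f"d_{v}": r for v, r in self.d.items()})
        return out


def parse_rates_text(text: str, net: BooleanNetwork,
                     default: float = 1.0) -> TransitionRates:
    """Read rates from flat ``u_<node>: value`` / ``d_<node>: value`` lines.

    Accepts the JSON/YAML-ish ``key: value`` or ``key = value`` dialect; nodes
    not mentioned keep ``default``.
    """
    rates = TransitionRates.uniform(net, default)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip().strip("{},\"'")
        if not line or line.startswith("#"):
            continue
        for sep in (":", "="):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ValueError(f"rates line {lineno}: expected 'u_<node>: value'")
        rates = rates.replace(**{key.strip().strip("\"'"): float(value)})
    return rates


# ---------------------------------------------------------------------------
# Transition table
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """Rate-independent list of all asynchronous transitions of a model.

    Arrays are parallel: arc ``m`` goes from 1-based state ``source[m]`` to
    ``target[m]`` by flipping 1-based node ``node[m]`` in direction
    ``direction[m]`` (+1 activation, -1 deactivation).  Sorted by source
    index, then node index.
    """

    n: int
    source: np.ndarray
    target: np.ndarray
    node: np.ndarray
    direction: np.ndarray
    _pattern: sp.csc_matrix | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return 2 ** self.n

    @property
    def n_transitions(self) -> int:
        return len(self.source)

    def out_degree(self) -> np.ndarray:
        """Number of outgoing arcs per state (index order)."""
        deg = np.zeros(self.n_states, dtype=np.int64)
        np.add.at(deg, self.source - 1, 1)
        return deg

    def terminal_states(self) -> np.ndarray:
        """1-based indices of sink states (no outgoing arcs; fixed points
        unless they sit inside a larger terminal cycle, which sinks cannot)."""
        return np.flatnonzero(self.out_degree() == 0) + 1

    def records(self) -> list[tuple[int, int, int, str]]:
        """(source, target, node, 'up'|'down') tuples, 1-based."""
        return [
            (int(s), int(t), int(k), "up" if d > 0 else "down")
            for s, t, k, d in zip(self.source, self.target, self.node, self.direction)
        ]


def enumerate_transitions(net: BooleanNetwork,
                          max_states: int | None = None) -> TransitionTable:
    """List every asynchronous single-node flip of the model.

    Vectorized over the full state space: for each node *k* the rule truth
    table is compared against the node's current bit in all 2^n states at
    once.  Raises ``ValueError`` if 2^n exceeds ``max_states``.
    """
    nu = net.n_states
    if max_states is not None and nu > max_states:
        raise ValueError(f"state space of {nu} states exceeds cap {max_states}")
    states = net.all_states()
    sources, targets, nodes, directions = [], [], [], []
    s_idx = np.arange(nu, dtype=np.int64)
    for k in range(1, net.n + 1):
        current = states[:, k - 1].astype(np.int64)
        updated = rule_truth_table(net, k).astype(np.int64)
        flips = np.flatnonzero(updated != current)
        if flips.size == 0:
            continue
        bit = np.int64(1 << (net.n - k))
        flip_dir = 1 - 2 * current[flips]          # +1 if 0->1, -1 if 1->0
        sources.append(s_idx[flips])
        targets.append(s_idx[flips] + flip_dir * bit)
        nodes.append(np.full(flips.size, k, dtype=np.int64))
        directions.append(flip_dir)
    if sources:
        source = np.concatenate(sources) + 1
        target = np.concatenate(targets) + 1
        node = np.concatenate(nodes)
        direction = np.concatenate(directions)
        order = np.lexsort((node, source))
        table = TransitionTable(net.n, source[order], target[order],
                                node[order], direction[order])
    else:
        empty = np.empty(0, dtype=np.int64)
        table = TransitionTable(net.n, empty, empty.copy(), empty.copy(), empty.copy())
    return table


# ---------------------------------------------------------------------------
# Kinetic matrix
# ---------------------------------------------------------------------------

def _arc_rates(table: TransitionTable, rates: TransitionRates,
               node_names: list[str]) -> np.ndarray:
    u = np.array([rates.u[v] for v in node_names])
    d = np.array([rates.d[v] for v in node_names])
    k = table.node - 1
    return np.where(table.direction > 0, u[k], d[k])


def build_kinetic_matrix(table: TransitionTable, rates: TransitionRates,
                         net: BooleanNetwork) -> sp.csc_matrix:
    """Assemble the sparse kinetic matrix *K* (CSC, 2^n x 2^n).

    ``K[j, i]`` is the rate of ``S_i → S_j``; diagonals close the columns to
    zero sum.  Zero-rate arcs (knockouts) are dropped from the pattern, since
    they change reachability.
    """
    rates.validate_for(net)
    nu = table.n_states
    vals = _arc_rates(table, rates, net.nodes)
    keep = vals > 0
    rows = table.target[keep] - 1
    cols = table.source[keep] - 1
    vals = vals[keep]
    out_rate = np.zeros(nu)
    np.add.at(out_rate, cols, vals)
    diag_idx = np.arange(nu, dtype=np.int64)
    K = sp.csc_matrix(
        (np.concatenate([vals, -out_rate]),
         (np.concatenate([rows, diag_idx]), np.concatenate([cols, diag_idx]))),
        shape=(nu, nu),
    )
    K.sum_duplicates()
    K.eliminate_zeros()      # sinks contribute stored-zero diagonals otherwise
    return K


def refresh_kinetic_matrix(table: TransitionTable, rates: TransitionRates,
                           net: BooleanNetwork) -> sp.csc_matrix:
    """Rebuild *K* for new rates, reusing the cached arc structure.

    When all rates are strictly positive the sparsity pattern is identical
    across parameter sets and only values are refilled; with zero rates the
    pattern itself changes and a full rebuild happens.
    """
    return build_kinetic_matrix(table, rates, net)


def check_column_sums(K: sp.spmatrix) -> float:
    """Max |column sum| of K, which must vanish for a proper Laplacian."""
    colsum = np.asarray(abs(K).max(axis=0).todense()).ravel()
    scale = np.maximum(colsum, 1.0)
    return float(np.max(np.abs(np.asarray(K.sum(axis=0)).ravel()) / scale))


# ---------------------------------------------------------------------------
# Weakly connected subgraphs
# ---------------------------------------------------------------------------

def split_subgraphs(table: TransitionTable) -> list[np.ndarray]:
    """Partition the 2^n states into weakly connected components.

    Models with non-dynamic input nodes have state spaces that split into
    disconnected subgraphs (one per input combination); each component can be
    solved independently.  States with no arcs are singleton components.
    Components are ordered by their smallest member state; members ascend.
    Returned indices are 1-based.
    """
    nu = table.n_states
    graph = sp.coo_matrix(
        (np.ones(table.n_transitions), (table.source - 1, table.target - 1)),
        shape=(nu, nu),
    )
    n_comp, labels = sp.csgraph.connected_components(graph, directed=True,
                                                     connection="weak")
    comps: list[np.ndarray] = [None] * n_comp
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    boundaries = np.searchsorted(sorted_labels, np.arange(n_comp + 1))
    for c in range(n_comp):
        comps[c] = np.sort(order[boundaries[c]:boundaries[c + 1]]) + 1
    comps.sort(key=lambda members: int(members[0]))
    return comps


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

def validate_probability_vector(x: np.ndarray, nu: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (nu,):
        raise ValueError(f"probability vector must have length {nu}")
    if (x < -PROB_ATOL).any() or (x > 1 + PROB_ATOL).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {x.sum()!r}, not 1")
    return np.clip(x, 0.0, 1.0)


def make_initial_condition(net: BooleanNetwork,
                           fixed: dict[str, int] | None = None,
                           explicit: np.ndarray | None = None) -> np.ndarray:
    """Build the initial probability vector ``x(0)`` over the 2^n states.

    ``fixed`` pins a subset of nodes to 0/1; probability is spread uniformly
    over all consistent states (a full assignment gives a point mass, an
    empty one the uniform distribution).  Alternatively an ``explicit``
    vector is validated and used as-is.
    """
    nu = net.n_states
    if explicit is not None:
        if fixed:
            raise ValueError("give either fixed node values or an explicit vector")
        return validate_probability_vector(explicit, nu)
    fixed = fixed or {}
    mask = np.ones(nu, dtype=bool)
    states = net.all_states()
    for name, value in fixed.items():
        j = net.node_index(name)
        if value not in (0, 1):
            raise ValueError(f"fixed value for {name!r} must be 0 or 1")
        mask &= states[:, j] == value
    x0 = np.zeros(nu)
    x0[mask] = 1.0 / mask.sum()
    return x0


def parse_initial_condition_string(net: BooleanNetwork, text: str) -> np.ndarray:
    """Parse a CLI-style initial condition such as ``"A=1,B=0"`` or ``"uniform"``."""
    text = text.strip()
    if text.lower() in ("", "uniform"):
        return make_initial_condition(net)
    fixed = {}
    for item in text.split(","):
        name, _, value = item.partition("=")
        if not value.strip():
            raise ValueError(f"bad initial-condition item {item!r}; expected NODE=0|1")
        fixed[name.strip()] = int(value)
    return make_initial_condition(net, fixed)
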