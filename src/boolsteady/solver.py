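"""Exact stationary solutions of the master equation via nullspace construction.

The probabilities of the 2^n states of an asynchronous continuous-time Boolean
model obey the linear master equation ``dx/dt = K x``.  Because every
trajectory of such a chain is eventually absorbed into a terminal strongly
connected component (SCC) of the state transition graph, the stationary
solution for any initial condition is

    x* = R · L · x(0)

where R and L are the right and left nullspaces of K, normalized so that
``L · R = I_q`` (q = number of terminal SCCs = number of attractors).  Generic
eigen-solvers do not produce this normalization; instead both kernels are read
off the graph structure after topological sorting:

* the states are permuted so terminal-SCC members occupy the last positions,
  giving the block form ``K' = [[N, 0], [B, T]]``;
* each column of R places total probability 1 on one attractor — a single 1
  for a fixed point, the within-cycle stationary distribution for a cyclic
  attractor (block V; the transient block Y is zero);
* U is the 0/1 indicator transpose of V (so U·V = I_q), and the remaining
  block of L holds the absorption probabilities X = −U·B·N⁻¹, obtained here
  by sparse triangular or LU solves of X·N = −U·B rather than inverting N.

Row ``a`` of X gives, for every transient state, the probability of ending in
attractor ``a``; its columns therefore sum to one.

Disconnected subgraphs (models with input nodes) are solved independently and
only when they carry initial probability mass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_io import BooleanNetwork
from .stg import (
    TransitionRates,
    TransitionTable,
    build_kinetic_matrix,
    enumerate_transitions,
    make_initial_condition,
    split_subgraphs,
    validate_probability_vector,
)

__all__ = [
    "SortedSTG",
    "KernelPair",
    "Attractor",
    "StationaryResult",
    "ExactSolver",
    "condense_and_sort",
    "reorder_blocks",
    "terminal_distribution",
    "build_right_kernel",
    "build_left_kernel",
    "stationary_solution",
    "node_probabilities",
    "solve",
    "KERNEL_ATOL",
]

#: Absolute tolerance for kernel/conservation identities; residuals between
#: this and WARN_ATOL trigger a warning rather than an error.
KERNEL_ATOL = 1e-9
WARN_ATOL = 1e-6

#: Above this many states per terminal SCC the within-cycle distribution is
#: solved sparsely instead of densely.
_DENSE_SCC_LIMIT = 1500


# ---------------------------------------------------------------------------
# Topological sorting of the (meta)graph
# ---------------------------------------------------------------------------

@dataclass
class SortedSTG:
    """Topologically sorted view of one weakly connected piece of the STG.

    ``order[p]`` is the original 1-based state index at sorted position ``p``
    (0-based).  Transient states occupy positions ``0..u-1``; the members of
    the q terminal SCCs fill the remaining positions, each SCC contiguous.
    """

    states: np.ndarray            # original 1-based indices, ascending
    order: np.ndarray             # original 1-based index per sorted position
    u: int                        # number of non-terminal (transient) states
    terminal_sccs: list[np.ndarray]  # original 1-based members, ascending
    scc_id: dict[int, int] = field(repr=False)  # original index -> SCC label

    @property
    def size(self) -> int:
        return len(self.order)

    @property
    def q(self) -> int:
        return len(self.terminal_sccs)

    def position(self) -> dict[int, int]:
        """Original 1-based state index -> sorted position (0-based)."""
        return {int(s): p for p, s in enumerate(self.order)}


def _scc_chain_order(members: list[int], succ: dict[int, list[int]]) -> list[int]:
    """Break an SCC into a DFS spanning path to push K' toward triangularity."""
    member_set = set(members)
    start = min(members)
    seen = {start}
    path = [start]
    stack = [start]
    while stack:
        node = stack[-1]
        nxt = None
        for t in succ.get(node, ()):
            if t in member_set and t not in seen:
                nxt = t
                break
        if nxt is None:
            stack.pop()
        else:
            seen.add(nxt)
            path.append(nxt)
            stack.append(nxt)
    return path


def condense_and_sort(table: TransitionTable,
                      states: np.ndarray | None = None,
                      chain_reorder: bool = False) -> SortedSTG:
    """Condense the STG into SCCs and topologically sort the metagraph.

    ``states`` restricts the computation to one weakly connected component
    (1-based indices); by default the whole state space is sorted.  Members of
    multi-state SCCs are placed contiguously, in ascending original index, or
    along a DFS spanning path when ``chain_reorder`` is set (the stationary
    result is identical either way; chaining only improves triangularity).
    Ties between incomparable SCCs are broken by smallest original member, so
    the permutation is deterministic.
    """
    if states is None:
        states = np.arange(1, table.n_states + 1, dtype=np.int64)
    states = np.asarray(sorted(int(s) for s in states), dtype=np.int64)
    state_set = set(states.tolist())
    G = nx.DiGraph()
    G.add_nodes_from(states.tolist())
    succ: dict[int, list[int]] = {}
    for s, t in zip(table.source, table.target):
        s, t = int(s), int(t)
        if s in state_set:
            G.add_edge(s, t)
            succ.setdefault(s, []).append(t)
    for lst in succ.values():
        lst.sort()

    cond = nx.condensation(G)
    # deterministic topological order of the metagraph, smallest member first
    topo = list(nx.lexicographical_topological_sort(
        cond, key=lambda c: min(cond.nodes[c]["members"])))
    scc_id = {}
    for c in cond.nodes:
        for s in cond.nodes[c]["members"]:
            scc_id[int(s)] = int(c)
    terminal_labels = {c for c in cond.nodes if cond.out_degree(c) == 0}

    def scc_members(c: int) -> list[int]:
        members = sorted(int(s) for s in cond.nodes[c]["members"])
        if chain_reorder and len(members) > 1:
            return _scc_chain_order(members, succ)
        return members

    order: list[int] = []
    for c in topo:
        if c not in terminal_labels:
            order.extend(scc_members(c))
    u = len(order)
    # terminal SCCs have no outgoing arcs, so any order among them preserves
    # the sorting invariant; smallest-member order keeps results deterministic
    terminal_sccs: list[np.ndarray] = []
    for c in sorted(terminal_labels, key=lambda c: min(cond.nodes[c]["members"])):
        members = scc_members(c)
        order.extend(members)
        terminal_sccs.append(np.asarray(sorted(members), dtype=np.int64))
    return SortedSTG(states=states, order=np.asarray(order, dtype=np.int64),
                     u=u, terminal_sccs=terminal_sccs, scc_id=scc_id)


# ---------------------------------------------------------------------------
# Block decomposition K' = [[N, 0], [B, T]]
# ---------------------------------------------------------------------------

def reorder_blocks(K: sp.spmatrix, sorting: SortedSTG
                   ) -> tuple[sp.csc_matrix, sp.csc_matrix, sp.csc_matrix]:
    """Permute K into sorted coordinates and split into blocks N, B, T.

    N (u x u) holds transitions among transient states, B ((m-u) x u) the
    flows from transient into terminal states, and T ((m-u) x (m-u)) the
    within-terminal dynamics.  The upper-right block must vanish (terminal
    SCCs have no outgoing arcs); a nonzero entry there indicates a sorting
    bug and raises ``RuntimeError``.
    """
    idx = sorting.order - 1
    Kp = K[np.ix_(idx, idx)].tocsc()
    u, m = sorting.u, sorting.size
    upper_right = Kp[:u, u:]
    if upper_right.nnz and abs(upper_right).max() > 0:
        raise RuntimeError("nonzero terminal→transient block; STG mis-sorted")
    N = Kp[:u, :u].tocsc()
    B = Kp[u:, :u].tocsc()
    T = Kp[u:, u:].tocsc()
    return N, B, T


# ---------------------------------------------------------------------------
# Within-attractor stationary distribution (cyclic attractors)
# ---------------------------------------------------------------------------

def terminal_distribution(T_scc: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution inside one terminal SCC.

    ``T_scc`` is the kinetic matrix restricted to the SCC's states: columns
    sum to zero and the states are mutually reachable, so its nullspace is
    one-dimensional with a strictly positive normalized basis vector (the
    matrix-tree / minors construction, computed here as a linear solve of the
    rank-deficient system with the normalization row appended).
    """
    T_scc = sp.csc_matrix(T_scc)
    m = T_scc.shape[0]
    if m == 1:
        if abs(T_scc[0, 0]) > 1e-12:
            raise ValueError("single terminal state with outgoing rate; not terminal")
        return np.array([1.0])
    colsum = np.asarray(T_scc.sum(axis=0)).ravel()
    scale = max(float(abs(T_scc).max()), 1.0)
    if np.max(np.abs(colsum)) > 1e-9 * scale:
        raise ValueError("columns do not sum to zero; not a closed terminal SCC")
    # replace the last equation by the normalization sum(v) = 1
    rhs = np.zeros(m)
    rhs[-1] = 1.0
    if m <= _DENSE_SCC_LIMIT:
        A = T_scc.toarray()
        A[-1, :] = 1.0
        v = np.linalg.solve(A, rhs)
    else:
        A = T_scc.tolil()
        A[-1, :] = 1.0
        v = spla.spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(v)) or np.min(v) < -1e-9:
        raise ValueError("terminal SCC solve failed; subgraph is not strongly connected")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@dataclass
class KernelPair:
    """Right/left nullspace pair in sorted coordinates, with L·R = I_q."""

    R: sp.csc_matrix   # m x q; top block Y = 0, bottom block V
    L: np.ndarray      # q x m; left block X (absorption probs), right block U
    u: int

    @property
    def q(self) -> int:
        return self.R.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Absorption probabilities: X[a, s] = P(attractor a | start s)."""
        return self.L[:, :self.u]


def build_right_kernel(sorting: SortedSTG, T: sp.spmatrix) -> sp.csc_matrix:
    """Column basis of the right nullspace: one probability column per attractor."""
    m, u = sorting.size, sorting.u
    rows, cols, vals = [], [], []
    offset = u
    for a, members in enumerate(sorting.terminal_sccs):
        k = len(members)
        if k == 1:
            rows.append(offset)
            cols.append(a)
            vals.append(1.0)
        else:
            block = T[offset - u:offset - u + k, offset - u:offset - u + k]
            v = terminal_distribution(block)
            rows.extend(range(offset, offset + k))
            cols.extend([a] * k)
            vals.extend(v.tolist())
        offset += k
    return sp.csc_matrix((vals, (rows, cols)), shape=(m, len(sorting.terminal_sccs)))


def build_left_kernel(R: sp.csc_matrix, N: sp.csc_matrix,
                      B: sp.csc_matrix, u: int) -> np.ndarray:
    """Row basis of the left nullspace, normalized against R.

    U is the indicator transpose of the terminal block V of R.  The transient
    block solves X·N = −U·B; N is lower triangular whenever the transient part
    of the sorted STG is acyclic, in which case a sparse triangular solve is
    used, otherwise a sparse LU factorization.  N is never inverted
    explicitly.
    """
    m, q = R.shape
    V = R[u:, :]
    U = V.T.sign().toarray()
    L = np.zeros((q, m))
    L[:, u:] = U
    if u:
        rhs = -(U @ B.toarray()).T           # u x q
        Nt = N.T.tocsr()
        strict_upper = sp.triu(N, k=1)
        if strict_upper.nnz == 0:
            Xt = spla.spsolve_triangular(Nt, rhs, lower=False)
        else:
            Xt = spla.splu(Nt.tocsc()).solve(rhs)
        L[:, :u] = Xt.T
    return L


def _verify_kernels(Kp: sp.csc_matrix, kernels: KernelPair) -> float:
    """Max residual of K'·R = 0, L·K' = 0 and L·R = I_q."""
    R, L = kernels.R, kernels.L
    scale = max(float(abs(Kp).max()), 1.0)
    res = max(
        float(np.abs((Kp @ R).toarray()).max(initial=0.0)) / scale,
        float(np.abs(L @ Kp).max(initial=0.0)) / scale,
        float(np.abs(L @ R.toarray() - np.eye(kernels.q)).max(initial=0.0)),
    )
    return res


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class Attractor:
    """One terminal SCC with its stationary probability."""

    kind: str                         # "fixed_point" | "cyclic"
    states: list[int]                 # original 1-based indices
    labels: list[str]                 # bit-string labels
    distribution: np.ndarray          # within-attractor probabilities (sum 1)
    probability: float                # total stationary probability
    subgraph: int                     # 1-based weakly connected component id


@dataclass
class StationaryResult:
    """Exact stationary solution of one model / rate set / initial condition."""

    net: BooleanNetwork
    x_star: np.ndarray                # stationary probability per state
    attractors: list[Attractor]
    node_probabilities: dict[str, float]
    subgraph_members: list[np.ndarray]

    def attractor_probabilities(self) -> dict[tuple[str, ...], float]:
        """Total probability per attractor, keyed by its state labels."""
        return {tuple(a.labels): a.probability for a in self.attractors}

    def state_probabilities(self) -> dict[str, float]:
        """Stationary probability per attractor state label (aggregated over
        subgraphs that share a bit pattern)."""
        out: dict[str, float] = {}
        for a in self.attractors:
            for label, p_rel in zip(a.labels, a.distribution):
                out[label] = out.get(label, 0.0) + a.probability * float(p_rel)
        return out

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.net.nodes),
            "attractors": [
                {
                    "type": a.kind,
                    "subgraph": a.subgraph,
                    "states": [
                        {
                            "index": int(s),
                            "bits": lab,
                            "probability": float(a.probability * w),
                        }
                        for s, lab, w in zip(a.states, a.labels, a.distribution)
                    ],
                    "total_probability": float(a.probability),
                }
                for a in self.attractors
            ],
            "node_probabilities": {k: float(v) for k, v in self.node_probabilities.items()},
        }

    def to_json(self) -> str:
        def _round(obj):
            if isinstance(obj, float):
                return float(f"{obj:.12g}")
            if isinstance(obj, dict):
                return {k: _round(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_round(v) for v in obj]
            return obj
        return json.dumps(_round(self.to_dict()), indent=2)

    def to_tsv(self) -> str:
        lines = ["kind\tsubgraph\tstate_index\tbits\tprobability"]
        for a in self.attractors:
            for s, lab, w in zip(a.states, a.labels, a.distribution):
                lines.append(
                    f"{a.kind}\t{a.subgraph}\t{s}\t{lab}\t{a.probability * w:.12g}")
        for name, p in self.node_probabilities.items():
            lines.append(f"node\t\t\t{name}\t{p:.12g}")
        return "\n".join(lines) + "\n"


def node_probabilities(net: BooleanNetwork, x_star: np.ndarray) -> dict[str, float]:
    """Stationary probability that each node equals 1.

    Weights every state's bit pattern by its stationary probability; since
    only attractor states carry stationary mass this is the sum over
    attractor states with the node ON.
    """
    states = net.all_states()
    probs = x_star @ states
    return {name: float(probs[j]) for j, name in enumerate(net.nodes)}


# ---------------------------------------------------------------------------
# Facade
# ---------------------------------------------------------------------------

class ExactSolver:
    """Reusable solver for one model.

    The transition table, the weakly-connected-component split and the
    per-component topological sorting depend only on the logic, not on the
    rate values, so they are computed once and reused across parameter sets
    (the dominant cost in parameter scans is otherwise regenerating this
    structure).  Rate sets containing zeros (knockouts) change reachability
    and therefore trigger a structure rebuild for that call only.
    """

    def __init__(self, net: BooleanNetwork, max_states: int | None = None,
                 chain_reorder: bool = False):
        self.net = net
        self.table = enumerate_transitions(net, max_states=max_states)
        self.components = split_subgraphs(self.table)
        self.chain_reorder = chain_reorder
        self._sorted: dict[int, SortedSTG] = {}

    # -- structure ---------------------------------------------------------

    def sorted_component(self, comp: int) -> SortedSTG:
        if comp not in self._sorted:
            self._sorted[comp] = condense_and_sort(
                self.table, self.components[comp], chain_reorder=self.chain_reorder)
        return self._sorted[comp]

    def _effective_structure(self, rates: TransitionRates):
        """(table, components, sorter) honouring zero-rate knockouts."""
        vals = np.array([rates.get(f"{'u' if d > 0 else 'd'}_{self.net.nodes[k - 1]}")
                         for k, d in zip(self.table.node, self.table.direction)])
        if np.all(vals > 0):
            return self.table, self.components, self.sorted_component
        keep = vals > 0
        table = TransitionTable(self.table.n, self.table.source[keep],
                                self.table.target[keep], self.table.node[keep],
                                self.table.direction[keep])
        components = split_subgraphs(table)
        sorter = lambda c: condense_and_sort(table, components[c],
                                             chain_reorder=self.chain_reorder)
        return table, components, sorter

    # -- solving -----------------------------------------------------------

    def solve(self, rates: TransitionRates, x0: np.ndarray,
              include_empty: bool = False) -> StationaryResult:
        """Exact stationary solution ``x* = R·L·x(0)``, per occupied subgraph."""
        net = self.net
        x0 = validate_probability_vector(x0, net.n_states)
        table, components, sorter = self._effective_structure(rates)
        K = build_kinetic_matrix(table, rates, net)
        x_star = np.zeros(net.n_states)
        attractors: list[Attractor] = []
        for ci, members in enumerate(components):
            mass = float(x0[members - 1].sum())
            if mass <= 0.0 and not include_empty:
                continue
            sorting = sorter(ci)
            N, B, T = reorder_blocks(K, sorting)
            R = build_right_kernel(sorting, T)
            L = build_left_kernel(R, N, B, sorting.u)
            kernels = KernelPair(R=R, L=L, u=sorting.u)
            idx = sorting.order - 1
            Kp = K[np.ix_(idx, idx)].tocsc()
            res = _verify_kernels(Kp, kernels)
            if res > WARN_ATOL:
                raise RuntimeError(f"kernel residual {res:.3e} exceeds {WARN_ATOL}")
            if res > KERNEL_ATOL:
                warnings.warn(f"kernel residual {res:.3e} above {KERNEL_ATOL}",
                              RuntimeWarning, stacklevel=2)
            weights = L @ x0[idx]                  # probability per attractor
            xs = R @ weights
            x_star[idx] += xs
            offset = sorting.u
            for a, scc in enumerate(sorting.terminal_sccs):
                k = len(scc)
                dist = np.asarray(R[offset:offset + k, a].toarray()).ravel()
                member_order = sorting.order[offset:offset + k]
                # report members in ascending original index
                asc = np.argsort(member_order)
                attractors.append(Attractor(
                    kind="fixed_point" if k == 1 else "cyclic",
                    states=[int(s) for s in member_order[asc]],
                    labels=[net.state_label(int(s)) for s in member_order[asc]],
                    distribution=dist[asc],
                    probability=float(weights[a]),
                    subgraph=ci + 1,
                ))
                offset += k
        total = x_star.sum()
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"stationary probabilities sum to {total!r}")
        return StationaryResult(
            net=net,
            x_star=x_star,
            attractors=attractors,
            node_probabilities=node_probabilities(net, x_star),
            subgraph_members=list(components),
        )


def stationary_solution(R: sp.csc_matrix, L: np.ndarray,
                        x0: np.ndarray) -> np.ndarray:
    """Apply ``x* = R·L·x(0)`` in sorted coordinates (low-level helper)."""
    return np.asarray(R @ (L @ np.asarray(x0, dtype=float)))


def solve(net: BooleanNetwork, rates: TransitionRates | None = None,
          init: dict[str, int] | np.ndarray | None = None,
          include_empty: bool = False,
          max_states: int | None = None) -> StationaryResult:
    """One-shot facade: enumerate → K → sort → kernels → x* → projections.

    ``rates`` defaults to all 1; ``init`` may be a partial node assignment
    (uniform over consistent states) or an explicit probability vector.
    """
    rates = rates or TransitionRates.uniform(net)
    if init is None or isinstance(init, dict):
        x0 = make_initial_condition(net, fixed=init)
    else:
        x0 = make_initial_condition(net, explicit=init)
    return ExactSolver(net, max_states=max_states).solve(
        rates, x0, include_empty=include_empty)
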