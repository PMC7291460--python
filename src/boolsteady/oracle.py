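"""Independent validators for the exact solver.

Three cross-checks that share no code with the nullspace construction:

* :func:`gillespie_simulate` — continuous-time kinetic Monte Carlo sampling of
  trajectories (exponential waiting times, categorical flip choice), the
  method the exact calculation replaces;
* :func:`dense_transient` — the matrix-exponential solution
  ``x(t) = exp(Kt)·x(0)`` of the master equation, evaluated densely;
* :func:`dense_absorption` — first-step analysis on the embedded jump chain
  combined with dense nullspace extraction for cyclic attractors.

All three are size-guarded; they are validation devices for small models, not
the production path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .model_io import BooleanNetwork
from .stg import (
    TransitionRates,
    TransitionTable,
    enumerate_transitions,
    validate_probability_vector,
)

__all__ = [
    "SimulationSettings",
    "SimulationEstimate",
    "gillespie_simulate",
    "dense_transient",
    "dense_absorption",
    "DENSE_STATE_LIMIT",
]

DENSE_STATE_LIMIT = 4096


@dataclass
class SimulationSettings:
    """Monte Carlo protocol: trajectory count, horizon, recording step, seed."""

    n_trajectories: int = 10_000
    t_max: float = 50.0
    record_dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")
        if self.t_max <= 0 or self.record_dt <= 0:
            raise ValueError("t_max and record_dt must be positive")


@dataclass
class SimulationEstimate:
    """Monte Carlo occupancy estimates with binomial standard errors.

    ``state_probs`` are end-state frequencies at ``t_max``;
    ``time_avg_probs`` average occupancy over the second half of the horizon
    (the windowed estimator appropriate for cyclic attractors).  Both are
    reported because sampling toolchains differ in which one they print.
    """

    state_probs: np.ndarray
    state_se: np.ndarray
    time_avg_probs: np.ndarray
    node_probs: dict[str, float]
    node_se: dict[str, float]
    n_trajectories: int


def _per_state_moves(table: TransitionTable, rates: TransitionRates,
                     net: BooleanNetwork):
    """Per-state arrays of (targets, rates, total rate), 0-based states."""
    nu = table.n_states
    u = np.array([rates.u[v] for v in net.nodes])
    d = np.array([rates.d[v] for v in net.nodes])
    arc_rate = np.where(table.direction > 0, u[table.node - 1], d[table.node - 1])
    keep = arc_rate > 0
    src = table.source[keep] - 1
    tgt = table.target[keep] - 1
    arc_rate = arc_rate[keep]
    order = np.argsort(src, kind="stable")
    src, tgt, arc_rate = src[order], tgt[order], arc_rate[order]
    bounds = np.searchsorted(src, np.arange(nu + 1))
    targets = [tgt[bounds[s]:bounds[s + 1]] for s in range(nu)]
    rate_list = [arc_rate[bounds[s]:bounds[s + 1]] for s in range(nu)]
    totals = np.array([r.sum() for r in rate_list])
    return targets, rate_list, totals


def gillespie_simulate(net: BooleanNetwork, rates: TransitionRates,
                       x0: np.ndarray,
                       settings: SimulationSettings) -> SimulationEstimate:
    """Kinetic Monte Carlo estimate of the stationary distribution.

    Each trajectory starts from a state drawn from ``x0``; at every step the
    enabled single-node flips define an exponential waiting time with the
    total rate and a categorical choice proportional to the individual rates.
    A trajectory halts early once it reaches a state with no enabled flips
    (a fixed point holds forever).  One master seed spawns per-trajectory
    substreams, so results do not depend on execution order.
    """
    rates.validate_for(net)
    x0 = validate_probability_vector(x0, net.n_states)
    table = enumerate_transitions(net)
    targets, rate_list, totals = _per_state_moves(table, rates, net)
    nu = net.n_states
    n_traj = settings.n_trajectories
    t_max = settings.t_max
    window_start = t_max / 2.0

    master = np.random.SeedSequence(settings.seed)
    start_rng = np.random.default_rng(master.spawn(1)[0])
    starts = start_rng.choice(nu, size=n_traj, p=x0)
    traj_seeds = master.spawn(n_traj)

    end_counts = np.zeros(nu)
    window_time = np.zeros(nu)
    for i in range(n_traj):
        rng = np.random.default_rng(traj_seeds[i])
        s = int(starts[i])
        t = 0.0
        while True:
            lam = totals[s]
            if lam <= 0.0:
                dwell_end = t_max
            else:
                dwell_end = t + rng.exponential(1.0 / lam)
            lo = max(t, window_start)
            hi = min(dwell_end, t_max)
            if hi > lo:
                window_time[s] += hi - lo
            if dwell_end >= t_max or lam <= 0.0:
                break
            t = dwell_end
            r = rate_list[s]
            s = int(targets[s][rng.choice(len(r), p=r / lam)])
        end_counts[s] += 1

    p = end_counts / n_traj
    se = np.sqrt(p * (1 - p) / n_traj)
    time_avg = window_time / (n_traj * (t_max - window_start))
    states = net.all_states()
    node_p = p @ states
    node_probs = {v: float(node_p[j]) for j, v in enumerate(net.nodes)}
    node_se = {v: float(np.sqrt(node_p[j] * (1 - node_p[j]) / n_traj))
               for j, v in enumerate(net.nodes)}
    return SimulationEstimate(
        state_probs=p, state_se=se, time_avg_probs=time_avg,
        node_probs=node_probs, node_se=node_se, n_trajectories=n_traj,
    )


def dense_transient(K: sp.spmatrix | np.ndarray, x0: np.ndarray,
                    t: float) -> np.ndarray:
    """Transient solution ``x(t) = exp(Kt)·x(0)`` by dense matrix exponential."""
    K = sp.csc_matrix(K)
    nu = K.shape[0]
    if nu > DENSE_STATE_LIMIT:
        raise ValueError(f"dense oracle limited to {DENSE_STATE_LIMIT} states")
    x0 = validate_probability_vector(x0, nu)
    return scipy.linalg.expm(K.toarray() * t) @ x0


def dense_absorption(K: sp.spmatrix | np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Stationary solution by first-step analysis on the embedded jump chain.

    Terminal SCCs are found with a strong-connectivity sweep; transient mass
    is routed to them by solving ``(I − Q)·A = Rj`` for the jump-chain
    absorption probabilities, and mass inside a cyclic attractor is spread
    along the dense nullspace of the cycle's Laplacian.  Entirely independent
    of the block-kernel construction in :mod:`boolsteady.solver`.
    """
    K = sp.csc_matrix(K)
    nu = K.shape[0]
    if nu > DENSE_STATE_LIMIT:
        raise ValueError(f"dense oracle limited to {DENSE_STATE_LIMIT} states")
    x0 = validate_probability_vector(x0, nu)
    Kd = K.toarray()
    off = Kd.copy()
    np.fill_diagonal(off, 0.0)

    adj = sp.csr_matrix((off.T > 0).astype(np.int8))  # adj[i,j]: arc i -> j
    n_scc, labels = sp.csgraph.connected_components(adj, directed=True,
                                                    connection="strong")
    out_rate = -np.diag(Kd)
    # an SCC is terminal iff none of its states has an arc leaving the SCC
    terminal = np.ones(n_scc, dtype=bool)
    src, tgt = adj.nonzero()
    for s, t in zip(src, tgt):
        if labels[s] != labels[t]:
            terminal[labels[s]] = False
    terminal_ids = np.flatnonzero(terminal)
    transient_states = np.flatnonzero(~terminal[labels])
    x_star = np.zeros(nu)

    # absorption probabilities of transient states into each terminal SCC
    mass_into = np.zeros(n_scc)
    for a in terminal_ids:
        members = np.flatnonzero(labels == a)
        mass_into[a] = x0[members].sum()
    if transient_states.size:
        # jump[i, j] = P(i -> j) on the embedded chain, transient rows only
        jump = off.T[transient_states, :] / out_rate[transient_states, None]
        Q = jump[:, transient_states]
        Rj = np.zeros((transient_states.size, terminal_ids.size))
        for col, a in enumerate(terminal_ids):
            members = np.flatnonzero(labels == a)
            Rj[:, col] = jump[:, members].sum(axis=1)
        A = np.linalg.solve(np.eye(Q.shape[0]) - Q, Rj)
        for col, a in enumerate(terminal_ids):
            mass_into[a] += x0[transient_states] @ A[:, col]

    for a in terminal_ids:
        members = np.flatnonzero(labels == a)
        if members.size == 1:
            x_star[members[0]] = mass_into[a]
        else:
            sub = Kd[np.ix_(members, members)]
            ns = scipy.linalg.null_space(sub)
            if ns.shape[1] != 1:
                raise RuntimeError("terminal SCC nullspace is not one-dimensional")
            v = np.abs(ns[:, 0])
            x_star[members] = mass_into[a] * v / v.sum()
    return x_star
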