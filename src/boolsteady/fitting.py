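"""Fitting transition rates to target stationary probabilities.

Stationary probabilities are ratios of high-order polynomials in the rates,
so analytic gradients are impractical beyond toy sizes.  The workhorse is
gradient-free simulated annealing on the sum of squared errors (SSE) between
predicted and target probabilities, searched in log10-rate space (rates are
timescale ratios spanning decades).  A cheaper variant estimates the SSE
gradient numerically once, at the start point, and line-searches along that
fixed descent direction; it can diverge when the initial gradient is not
informative, and reports that instead of hiding it.

Targets may mix node probabilities (keyed by node name) and attractor-state
probabilities (keyed by bit-string label such as ``"011"``), unweighted by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import BooleanNetwork
from .solver import ExactSolver, StationaryResult
from .stg import TransitionRates, make_initial_condition

__all__ = ["FitProblem", "FitResult", "sse_objective", "fit_anneal", "fit_grad_init"]

DEFAULT_BOUNDS = (1e-3, 1e3)


@dataclass
class FitProblem:
    """A rate-fitting task: model, initial condition, free rates, targets."""

    net: BooleanNetwork
    free: list[str]                       # flat rate names, e.g. "u_B"
    targets: dict[str, float]             # node name or state bit-label -> prob
    init: dict[str, int] | np.ndarray | None = None
    base_rates: TransitionRates | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.free:
            raise ValueError("free parameter set must be nonempty")
        if self.base_rates is None:
            self.base_rates = TransitionRates.uniform(self.net)
        for name in self.free:
            self.base_rates.get(name)     # raises on unknown rate names
        for key, value in self.targets.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"target for {key!r} must lie in [0, 1]")
            self._target_kind(key)
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must be positive and ordered")

    def _target_kind(self, key: str) -> str:
        if key in self.net.nodes:
            return "node"
        if set(key) <= {"0", "1"} and len(key) == self.net.n:
            return "state"
        raise KeyError(f"target {key!r} is neither a node name nor an n-bit state label")

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([np.log10(self.bounds.get(p, DEFAULT_BOUNDS)[0]) for p in self.free])
        hi = np.array([np.log10(self.bounds.get(p, DEFAULT_BOUNDS)[1]) for p in self.free])
        return lo, hi

    def initial_point(self) -> np.ndarray:
        """Start point in log10-rate space: the base rates, clipped to bounds."""
        lo, hi = self.log_bounds()
        x = np.array([np.log10(max(self.base_rates.get(p), 1e-300)) for p in self.free])
        return np.clip(x, lo, hi)

    def x0_vector(self) -> np.ndarray:
        if self.init is None or isinstance(self.init, dict):
            return make_initial_condition(self.net, fixed=self.init)
        return make_initial_condition(self.net, explicit=self.init)

    def predicted(self, result: StationaryResult) -> dict[str, float]:
        states = result.state_probabilities()
        out = {}
        for key in self.targets:
            if key in self.net.nodes:
                out[key] = result.node_probabilities[key]
            else:
                out[key] = states.get(key, 0.0)
        return out


class _Evaluator:
    """SSE evaluation with the STG structure cached across calls."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.solver = ExactSolver(problem.net)
        self.x0 = problem.x0_vector()

    def rates_at(self, log_x: np.ndarray) -> TransitionRates:
        return self.problem.base_rates.replace(
            **{p: 10.0 ** v for p, v in zip(self.problem.free, log_x)})

    def sse(self, log_x: np.ndarray) -> float:
        result = self.solver.solve(self.rates_at(log_x), self.x0)
        predicted = self.problem.predicted(result)
        return float(sum(
            self.problem.weights.get(key, 1.0) * (predicted[key] - target) ** 2
            for key, target in self.problem.targets.items()))


def sse_objective(problem: FitProblem, rates: TransitionRates | dict[str, float]
                  ) -> float:
    """Sum of squared errors between solved and target probabilities."""
    if isinstance(rates, dict):
        rates = problem.base_rates.replace(**rates)
    evaluator = _Evaluator(problem)
    result = evaluator.solver.solve(rates, evaluator.x0)
    predicted = problem.predicted(result)
    return float(sum(
        problem.weights.get(key, 1.0) * (predicted[key] - target) ** 2
        for key, target in problem.targets.items()))


@dataclass
class FitResult:
    """Outcome of a fit: best rates, SSE, and the per-iteration SSE trace."""

    method: str
    best_rates: dict[str, float]
    best_sse: float
    trace: np.ndarray
    seed: int | None
    n_iterations: int
    diverged: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "best_rates": {k: float(v) for k, v in self.best_rates.items()},
            "best_sse": float(self.best_sse),
            "n_iterations": int(self.n_iterations),
            "seed": self.seed,
            "diverged": bool(self.diverged),
            "sse_trace": [float(v) for v in self.trace],
        }


def fit_anneal(problem: FitProblem, n_iter: int = 10_000, seed: int = 0,
               t0: float | None = None, alpha: float = 0.995,
               sigma: float = 0.1, tol: float = 0.0) -> FitResult:
    """Simulated annealing on the SSE with geometric cooling.

    Proposals are Gaussian steps of ``sigma`` decades in log10-rate space
    (multiplicative log-normal on the rates), clipped to the bounds; moves
    are Metropolis-accepted at temperature ``T_k = T0·alpha^k`` with ``T0``
    defaulting to the initial SSE.  At T0 = 0 this degenerates to greedy
    descent.  Stops early once SSE < ``tol``.  Fully reproducible under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    ev = _Evaluator(problem)
    lo, hi = problem.log_bounds()
    x = problem.initial_point()
    current = ev.sse(x)
    best_x, best = x.copy(), current
    if t0 is None:
        t0 = current
    trace = [current]
    for k in range(n_iter):
        if best < tol:
            break
        proposal = np.clip(x + rng.normal(0.0, sigma, size=len(x)), lo, hi)
        candidate = ev.sse(proposal)
        delta = candidate - current
        temperature = t0 * alpha ** k
        if delta <= 0 or (temperature > 0
                          and rng.random() < np.exp(-delta / temperature)):
            x, current = proposal, candidate
            if current < best:
                best_x, best = x.copy(), current
        trace.append(current)
    return FitResult(
        method="anneal",
        best_rates={p: float(10.0 ** v) for p, v in zip(problem.free, best_x)},
        best_sse=best,
        trace=np.asarray(trace),
        seed=seed,
        n_iterations=len(trace) - 1,
    )


def fit_grad_init(problem: FitProblem, step: float = 0.1,
                  h: float = 1e-3, gtol: float = 1e-8, div_tol: float = 0.1,
                  max_steps: int = 200, seed: int | None = None) -> FitResult:
    """Descent along the initial numerical gradient of the SSE.

    The central-difference gradient (step ``h`` decades) is computed once at
    the start point; the fixed direction is then line-searched with step
    halving.  Because the direction is never re-estimated, the walk can
    overshoot into ascent; any candidate whose SSE exceeds the starting SSE
    by more than a relative ``div_tol`` — or a direction that never improves
    at all — sets the ``diverged`` flag on the result (the best-so-far point
    is still returned).
    """
    ev = _Evaluator(problem)
    lo, hi = problem.log_bounds()
    x = problem.initial_point()
    start_sse = ev.sse(x)
    trace = [start_sse]
    grad = np.zeros(len(x))
    for j in range(len(x)):
        e = np.zeros(len(x))
        e[j] = h
        grad[j] = (ev.sse(np.clip(x + e, lo, hi)) - ev.sse(np.clip(x - e, lo, hi))) / (2 * h)
    gnorm = float(np.max(np.abs(grad)))
    if gnorm < gtol:
        return FitResult(method="grad_init", best_sse=start_sse, trace=np.asarray(trace),
                         best_rates={p: float(10.0 ** v) for p, v in zip(problem.free, x)},
                         seed=seed, n_iterations=0, diverged=False)
    direction = -grad / np.linalg.norm(grad)
    best_x, best = x.copy(), start_sse
    current_step = step
    improved_any = False
    overshoot = False
    for _ in range(max_steps):
        candidate_x = np.clip(best_x + current_step * direction, lo, hi)
        candidate = ev.sse(candidate_x)
        trace.append(candidate)
        if candidate > start_sse * (1.0 + div_tol) + 1e-15:
            overshoot = True
        if candidate < best - 1e-15:
            best_x, best = candidate_x, candidate
            improved_any = True
        else:
            current_step /= 2.0
            if current_step < 1e-4:
                break
    return FitResult(
        method="grad_init",
        best_rates={p: float(10.0 ** v) for p, v in zip(problem.free, best_x)},
        best_sse=best,
        trace=np.asarray(trace),
        seed=seed,
        n_iterations=len(trace) - 1,
        diverged=overshoot or not improved_any,
    )
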