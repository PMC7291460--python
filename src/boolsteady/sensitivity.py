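"""Sensitivity of stationary solutions to transition-rate values.

Transition rates are usually defaulted to 1, but stationary attractor
probabilities are rational functions of the rates and can depend on them
strongly.  This module quantifies that dependence:

* 1-D scans of a single rate over a grid, with a max−min variation screen
  (rates moving at least one output by more than a threshold are "significant");
* Latin Hypercube Sampling (LHS) of the multidimensional rate space,
  log-uniform over [0.1, 10] by default;
* per-rate coefficients of determination (R²) from univariate linear
  regression of each output on each sampled rate;
* first-order Sobol indices via the classical two-matrix column-replacement
  estimator (cost (p+2)·m solves);
* Pearson correlations between node probabilities across the sample, flagging
  perfectly correlated node pairs as model-reduction candidates.

Outputs are attractor-state probabilities (columns ``state:<bits>``) and node
probabilities (columns ``node:<name>``).  Everything is reproducible under a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model_io import BooleanNetwork
from .solver import ExactSolver, StationaryResult
from .stg import TransitionRates, make_initial_condition

__all__ = [
    "ScanResult",
    "ParameterSample",
    "SensitivityTable",
    "scan_1d",
    "lhs_sample",
    "lhs_evaluate",
    "regression_r2",
    "sobol_first_order",
    "sobol_indices",
    "node_correlations",
    "DEFAULT_RANGE",
    "VARIATION_THRESHOLD",
]

#: Default sampling range for rates: log-uniform over two decades around 1.
DEFAULT_RANGE = (0.1, 10.0, "log")

#: 1-D scan screening threshold on the max−min variation of any output.
VARIATION_THRESHOLD = 0.1


def _result_outputs(result: StationaryResult) -> dict[str, float]:
    out = {f"state:{label}": p for label, p in result.state_probabilities().items()}
    out.update({f"node:{name}": p for name, p in result.node_probabilities.items()})
    return out


def _normalize_init(net: BooleanNetwork, init) -> np.ndarray:
    if init is None or isinstance(init, dict):
        return make_initial_condition(net, fixed=init)
    return make_initial_condition(net, explicit=init)


# ---------------------------------------------------------------------------
# 1-D parameter scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Outputs of a 1-D scan of one transition rate over a grid."""

    parameter: str
    grid: np.ndarray
    outputs: pd.DataFrame   # index = grid values; columns = output names

    def variation(self) -> pd.Series:
        """max − min of every output across the grid (the screening statistic)."""
        return self.outputs.max(axis=0) - self.outputs.min(axis=0)

    def significant(self, threshold: float = VARIATION_THRESHOLD) -> bool:
        """Whether any node probability moves by more than ``threshold``."""
        node_cols = [c for c in self.outputs.columns if c.startswith("node:")]
        return bool((self.variation()[node_cols] > threshold).any())


def scan_1d(net: BooleanNetwork, base_rates: TransitionRates, init,
            param: str, grid) -> ScanResult:
    """Solve the model along a grid of values of one rate, others fixed."""
    base_rates.get(param)   # raises KeyError for unknown parameters
    grid = np.asarray(list(grid), dtype=float)
    if (grid < 0).any():
        raise ValueError("rate grid values must be >= 0")
    x0 = _normalize_init(net, init)
    solver = ExactSolver(net)
    rows = []
    for value in grid:
        result = solver.solve(base_rates.replace(**{param: value}), x0)
        rows.append(_result_outputs(result))
    outputs = pd.DataFrame(rows, index=pd.Index(grid, name=param)).fillna(0.0)
    return ScanResult(parameter=param, grid=grid, outputs=outputs)


# ---------------------------------------------------------------------------
# Latin Hypercube Sampling
# ---------------------------------------------------------------------------

@dataclass
class ParameterSample:
    """Stratified (m × p) sample of rate values.

    Each column has exactly one value per equal-probability bin of its range,
    on the declared scale (``linear`` or ``log``).
    """

    names: list[str]
    values: np.ndarray                   # m x p, on the natural rate scale
    ranges: dict[str, tuple[float, float, str]]
    seed: int
    unit: np.ndarray = field(repr=False, default=None)  # m x p in [0, 1)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def design_matrix(self) -> np.ndarray:
        """Values on the sampling scale (log10 for log-scaled parameters)."""
        cols = []
        for j, name in enumerate(self.names):
            _, _, scale = self.ranges[name]
            col = self.values[:, j]
            cols.append(np.log10(col) if scale == "log" else col)
        return np.stack(cols, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def _scale_unit(unit: np.ndarray, names: list[str],
                ranges: dict[str, tuple[float, float, str]]) -> np.ndarray:
    values = np.empty_like(unit)
    for j, name in enumerate(names):
        lo, hi, scale = ranges[name]
        if scale == "log":
            values[:, j] = 10 ** (np.log10(lo) + unit[:, j] * (np.log10(hi) - np.log10(lo)))
        else:
            values[:, j] = lo + unit[:, j] * (hi - lo)
    return values


def _check_ranges(ranges: dict) -> dict[str, tuple[float, float, str]]:
    out = {}
    for name, spec in ranges.items():
        if len(spec) == 2:
            lo, hi = spec
            scale = "log"
        else:
            lo, hi, scale = spec
        lo, hi = float(lo), float(hi)
        if scale not in ("linear", "log"):
            raise ValueError(f"scale for {name!r} must be 'linear' or 'log'")
        if not hi > lo or (scale == "log" and lo <= 0):
            raise ValueError(f"invalid range for {name!r}: ({lo}, {hi}, {scale})")
        out[name] = (lo, hi, scale)
    return out


def lhs_sample(ranges: dict, m: int, seed: int) -> ParameterSample:
    """Latin Hypercube sample of the rate space, reproducible under seed."""
    ranges = _check_ranges(ranges)
    names = list(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(m)
    return ParameterSample(names=names, values=_scale_unit(unit, names, ranges),
                           ranges=ranges, seed=seed, unit=unit)


def lhs_evaluate(net: BooleanNetwork, init, sample: ParameterSample,
                 base_rates: TransitionRates | None = None) -> pd.DataFrame:
    """Solve the model for every row of the sample; unsampled rates stay at base.

    The rate-independent STG structure is built once and reused across rows.
    """
    base_rates = base_rates or TransitionRates.uniform(net)
    x0 = _normalize_init(net, init)
    solver = ExactSolver(net)
    rows = []
    for i in range(sample.m):
        rates = base_rates.replace(
            **{name: sample.values[i, j] for j, name in enumerate(sample.names)})
        rows.append(_result_outputs(solver.solve(rates, x0)))
    return pd.DataFrame(rows).fillna(0.0)


# ---------------------------------------------------------------------------
# Regression R² and Sobol indices
# ---------------------------------------------------------------------------

@dataclass
class SensitivityTable:
    """Per-(parameter, output) sensitivity estimates.

    ``values`` holds the raw estimates (rows = parameters, columns =
    outputs); sampling noise can push Sobol estimates slightly outside
    [0, 1], so a clipped copy is provided alongside.  ``flags`` records
    degenerate outputs (zero variance).
    """

    kind: str                       # "r2" | "sobol_s1"
    values: pd.DataFrame
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def clipped(self) -> pd.DataFrame:
        return self.values.clip(0.0, 1.0)


def regression_r2(design: np.ndarray | pd.DataFrame,
                  outputs: pd.DataFrame,
                  parameter_names: list[str] | None = None) -> SensitivityTable:
    """Univariate OLS R² of each output against each parameter column.

    ``design`` is the sample on its sampling scale (use
    :meth:`ParameterSample.design_matrix`).  R² = 1 − SS_res/SS_tot reduces to
    the squared Pearson correlation for a single regressor; outputs with zero
    variance get R² = 0 and a flag.
    """
    if isinstance(design, ParameterSample):
        parameter_names = design.names
        design = design.design_matrix()
    if isinstance(design, pd.DataFrame):
        parameter_names = list(design.columns)
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    if design.shape[0] < 3:
        raise ValueError("need at least 3 sample rows for regression")
    if parameter_names is None:
        parameter_names = [f"p{j}" for j in range(design.shape[1])]
    Y = outputs.to_numpy(dtype=float)
    flags: dict[str, str] = {}
    r2 = np.zeros((design.shape[1], Y.shape[1]))
    y_var = Y.var(axis=0)
    x_var = design.var(axis=0)
    for jo, col in enumerate(outputs.columns):
        if y_var[jo] <= 0:
            flags[col] = "zero output variance; R2 defined as 0"
            continue
        for jp in range(design.shape[1]):
            if x_var[jp] <= 0:
                continue
            x = design[:, jp]
            y = Y[:, jo]
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            r2[jp, jo] = cov ** 2 / (x_var[jp] * y_var[jo])
    values = pd.DataFrame(r2, index=parameter_names, columns=outputs.columns)
    return SensitivityTable(kind="r2", values=values, flags=flags)


def sobol_indices(func, ranges: dict, m: int, seed: int,
                  output_names: list[str] | None = None) -> SensitivityTable:
    """First-order Sobol indices of ``func`` by column replacement.

    ``func`` maps an (m × p) matrix of parameter values to an (m × k) array
    of outputs.  Two independent LHS matrices M₁ and M₂ are drawn; for each
    parameter *i* the hybrid Nᵢ equals M₂ with column *i* taken from M₁, and

        S1ᵢ = (mean(y_{M₁}·y_{Nᵢ}) − mean(y_{M₁})·mean(y_{M₂})) / Var(y_{M₁})

    Zero-variance outputs are reported as S1 = 0 with a flag.
    """
    ranges = _check_ranges(ranges)
    names = list(ranges)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    m1 = lhs_sample(ranges, m, int(seeds[0]))
    m2 = lhs_sample(ranges, m, int(seeds[1]))
    y1 = np.atleast_2d(np.asarray(func(m1.values), dtype=float))
    if y1.shape[0] == 1 and m > 1:
        y1 = y1.T
    y2 = np.atleast_2d(np.asarray(func(m2.values), dtype=float))
    if y2.shape[0] == 1 and m > 1:
        y2 = y2.T
    k = y1.shape[1]
    if output_names is None:
        output_names = [f"y{j}" for j in range(k)]
    var1 = y1.var(axis=0)
    s1 = np.zeros((len(names), k))
    flags: dict[str, str] = {}
    for j, name in enumerate(output_names):
        if var1[j] <= 0:
            flags[name] = "zero output variance; S1 defined as 0"
    for i in range(len(names)):
        hybrid = m2.values.copy()
        hybrid[:, i] = m1.values[:, i]
        yn = np.atleast_2d(np.asarray(func(hybrid), dtype=float))
        if yn.shape[0] == 1 and m > 1:
            yn = yn.T
        for j in range(k):
            if var1[j] <= 0:
                continue
            s1[i, j] = ((y1[:, j] * yn[:, j]).mean()
                        - y1[:, j].mean() * y2[:, j].mean()) / var1[j]
    values = pd.DataFrame(s1, index=names, columns=output_names)
    return SensitivityTable(kind="sobol_s1", values=values, flags=flags)


def sobol_first_order(net: BooleanNetwork, init, ranges: dict,
                      base_rates: TransitionRates | None = None,
                      m: int = 1000, seed: int = 0) -> SensitivityTable:
    """First-order Sobol indices of the stationary outputs w.r.t. the rates."""
    ranges = _check_ranges(ranges)
    names = list(ranges)
    base_rates = base_rates or TransitionRates.uniform(net)
    x0 = _normalize_init(net, init)
    solver = ExactSolver(net)
    columns: list[str] | None = None

    def evaluate(matrix: np.ndarray) -> np.ndarray:
        nonlocal columns
        rows = []
        for row in matrix:
            rates = base_rates.replace(**dict(zip(names, row)))
            rows.append(_result_outputs(solver.solve(rates, x0)))
        frame = pd.DataFrame(rows).fillna(0.0)
        if columns is None:
            columns = list(frame.columns)
        return frame.reindex(columns=columns, fill_value=0.0).to_numpy()

    first = evaluate(lhs_sample(ranges, 2, seed).values)  # fix column order
    del first
    table = sobol_indices(evaluate, ranges, m, seed, output_names=columns)
    return table


# ---------------------------------------------------------------------------
# Node-probability correlations
# ---------------------------------------------------------------------------

def node_correlations(outputs: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict[str, list]]:
    """Pearson correlations between node probabilities across a sample.

    Node pairs whose probabilities are identical in every sampled parameter
    set (correlation ≡ 1) are flagged as model-reduction candidates;
    zero-variance nodes are listed as undefined rather than propagating NaN.
    """
    node_cols = [c for c in outputs.columns if c.startswith("node:")]
    frame = outputs[node_cols] if node_cols else outputs
    names = [c.removeprefix("node:") for c in frame.columns]
    if len(frame) < 3:
        raise ValueError("need at least 3 sample rows for correlations")
    X = frame.to_numpy(dtype=float)
    var = X.var(axis=0)
    k = X.shape[1]
    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            if var[a] <= 0 or var[b] <= 0:
                corr[a, b] = corr[b, a] = 0.0
            else:
                c = np.corrcoef(X[:, a], X[:, b])[0, 1]
                corr[a, b] = corr[b, a] = c
    identical = [
        (names[a], names[b])
        for a in range(k) for b in range(a + 1, k)
        if np.allclose(X[:, a], X[:, b], atol=1e-12)
    ]
    undefined = [names[a] for a in range(k) if var[a] <= 0]
    matrix = pd.DataFrame(corr, index=names, columns=names)
    return matrix, {"identical_pairs": identical, "zero_variance": undefined}
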