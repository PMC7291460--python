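# Methods

## Model class and conventions

A Boolean network is an ordered list of nodes with one NOT/AND/OR update rule
per node.  Under asynchronous continuous-time updating the system is a Markov
chain on the 2^n binary states: a transition `S → S'` exists when the two
states differ in exactly one node *j* and rule `f_j` applied to `S` disagrees
with the current value of `v_j`; its rate is the activation rate `u_j` when
the flip is 0→1 and the deactivation rate `d_j` when it is 1→0.  Rates have
units of 1/time and default to 1, i.e. all processes share one timescale
unless the user says otherwise.

State indexing is fixed throughout: the first node of the model file is the
most significant bit, and states carry 1-based decimal indices, `S_1 =
[00…0]` up to `S_{2^n} = [11…1]`.  The kinetic matrix uses the
chemical-kinetics column convention — `K[j,i]` holds the rate of `S_i → S_j`,
the diagonal closes each column to zero — so `dx/dt = K·x` conserves total
probability.  A configurable node cap (default 25) refuses models whose state
space cannot be held as a sparse matrix.

## Exact stationary solution

Every trajectory of such a chain is absorbed into a terminal SCC of the STG,
so the stationary solution for initial condition `x(0)` is `x* = R·L·x(0)`
with `K·R = 0`, `L·K = 0`, `L·R = I_q`.  Generic eigensolvers satisfy the
first two identities but not the normalization, so the kernels are instead
constructed from the graph:

1. **Condensation and sorting.**  SCCs are computed (networkx), the
   condensation DAG is topologically sorted with deterministic tie-breaking
   (smallest original member first), and members of multi-state SCCs are kept
   contiguous.  Terminal SCCs are placed last — they have no outgoing arcs,
   so any order among them preserves the sorting invariant; smallest-member
   order keeps runs reproducible.
2. **Block form.**  In sorted coordinates `K' = [[N, 0], [B, T]]`: `N` is the
   transient-transient block (lower triangular whenever the transient part is
   acyclic, which holds for most signalling models), `B` feeds the terminal
   states, `T` is the within-terminal dynamics.  A nonzero upper-right block
   is impossible by construction and treated as an internal error.
3. **Right kernel.**  One column per attractor: a single 1 for a fixed point;
   for a cyclic attractor the cycle's stationary distribution, obtained by
   solving the rank-deficient system `T_scc·v = 0, Σv = 1` with the
   normalization row replacing one equation (equivalent to the matrix-tree
   minors construction but without its factorial blow-up; dense below 1500
   states, sparse above).
4. **Left kernel.**  `U` is the 0/1 indicator transpose of the terminal block
   of `R`, giving `U·V = I_q`; the transient block solves `X·N = −U·B` by a
   sparse triangular solve when `N` is lower triangular and sparse LU
   otherwise.  `N` is never inverted explicitly.  Row *a* of `X` holds the
   absorption probabilities of every transient state into attractor *a*, so
   its columns sum to one — a property checked in the tests.

Disconnected subgraphs (models with frozen input nodes) are detected by a
weak-connectivity sweep and solved independently; subgraphs carrying no
initial probability are skipped, and their attractors reported with
probability 0 only on request.  How initial mass is spread over states
consistent with a partial node assignment is a modelling choice; the package
uses the uniform distribution, and an explicit probability vector can be
supplied instead.

The rate-independent structure (transition table, component split, sorting)
is cached per model and only numeric matrix values are refilled across
parameter sets — the dominant cost of scans otherwise.  Rate sets containing
zeros (knockouts) change reachability and trigger a structure rebuild for
that call.

**Numerical tolerances.**  Column sums of `K` must vanish to 1e−12
(relative).  The kernel identities and conservation `L·x* = L·x(0)` are
verified to 1e−9 on every solve; residuals between 1e−9 and 1e−6 emit a
warning, larger ones raise.  Probability vectors must normalize to 1e−9.

## Validators

Three independent cross-checks, sharing no code with the kernel construction:

* **Gillespie simulation** — exponential waiting times from the total enabled
  rate, categorical flip choice, early exit at fixed points; one master seed
  spawns per-trajectory substreams so results are order-independent.  Both
  end-state frequencies (with binomial standard errors) and
  second-half-of-horizon time-averaged occupancies are reported, since
  sampling toolchains differ in which estimator they print; the time average
  is the meaningful one for cyclic attractors.
* **Dense transient** — `x(t) = expm(K·t)·x(0)`, guarded to 4096 states.
* **Dense absorption** — first-step analysis `(I−Q)A = Rj` on the embedded
  jump chain, with within-cycle mass spread along the dense nullspace of the
  cycle's Laplacian.

The test suite requires three-way agreement to 1e−6 on all fixtures and on
random-network ensembles, and Gillespie agreement within 1% / 3·SE at 10,000
trajectories.

## Sensitivity analysis

Outputs are attractor-state probabilities and per-node probabilities (the
attractor bit patterns weighted by their probabilities).

* **1-D scans** solve the model along a grid of one rate; the screening
  statistic is the max−min variation of each output, with 0.1 as the default
  threshold for calling a rate significant.  A rate labelling no reachable
  arc leaves every output exactly constant, which the tests assert exactly.
* **LHS** uses `scipy.stats.qmc.LatinHypercube`; the default range is
  log-uniform over [0.1, 10] — two decades around the conventional rate of 1,
  matching the usual scan convention for these models.
* **R²** is univariate ordinary least squares of each output on each rate on
  its sampling scale (log10 for log-scaled rates); with one regressor this is
  the squared Pearson correlation.  Zero-variance outputs get R² = 0 plus a
  flag rather than NaN.
* **Sobol first-order indices** use the classical two-matrix
  column-replacement estimator: two independent LHS draws `M₁, M₂`, hybrids
  `Nᵢ` (column *i* of `M₁` into `M₂`), and
  `S1ᵢ = (mean(y₁·y_{Nᵢ}) − mean(y₁)·mean(y₂)) / Var(y₁)`, at cost
  `(p+2)·m` solves.  Estimates can fall slightly outside [0,1] by sampling
  noise; the raw and a clipped table are both returned.  On the analytic
  additive benchmark `y = 2x₁ + x₂` the estimator recovers the variance
  shares (0.8, 0.2) within ±0.05 at m = 1000.
* **Node correlations** across an LHS sample flag pairs with identical values
  in every parameter set as model-reduction candidates; zero-variance nodes
  are reported as undefined instead of propagating NaN.

## Rate fitting

The objective is the unweighted SSE between solved and target probabilities;
targets may mix node probabilities and attractor-state probabilities (weights
configurable).  Search happens in log10-rate space with default bounds
[10⁻³, 10³], because rates are timescale ratios spanning decades.

* **Simulated annealing** (default): Gaussian proposals of 0.1 decades,
  Metropolis acceptance under geometric cooling `T_k = T₀·0.995^k` with `T₀`
  equal to the initial SSE, 10⁴ iterations by default.  `T₀ = 0` degenerates
  to greedy descent.  Acceptance is by self-target recovery (SSE < 10⁻³),
  not by matching the generating rates — stationary solutions are generally
  non-identifiable in the rates.
* **Initial-gradient descent**: the central-difference SSE gradient is
  estimated once at the start point and the fixed direction line-searched
  with step halving.  Because the direction is never refreshed the walk can
  overshoot into ascent; any candidate exceeding the starting SSE by more
  than 10% (relative), or a direction that never improves, sets a `diverged`
  flag on the result while still returning the best point found.

## Synthetic fixtures and what the tests show

All tests run on programmatically generated models: the printed 3-node
example (three fixed points; every structural count and the stationary values
17/48, 18/48, 13/48 are hand-derivable), a 2-node ring whose whole state
space is one cyclic attractor, an input-split variant with disconnected
subgraphs, and random NOT/AND/OR networks of 3–8 nodes for property-based
ensembles (kernel identities on 100 models, three-way oracle agreement on
40–50).  Problem sizes were chosen so the full suite solves hundreds of
models in well under a minute: at n ≤ 8 the dense oracles are exact to
round-off, which is precisely what makes them useful as references.

These fixtures exercise every structural regime the method distinguishes
(fixed points, terminal cycles, non-terminal branching, disconnected
subgraphs, knockouts) but not the scale of curated biological models
(13–23 nodes, STGs to 2^23 states) — passing tests demonstrate correctness
of the construction, not large-model performance.  Published model encodings
can be supplied externally and run through the identical code path.

## Known limitations

* The full 2^n state space is enumerated; unreachable states are not pruned.
  The node cap (25) reflects sparse-matrix memory, not solver capability.
* Large non-terminal cycles make `N` far from triangular and push the LU
  solve toward its worst case.
* The Sobol estimator is first-order only; no total-order indices.
* Multi-valued logic and SBML-qual import are out of scope; BoolNet text is
  the only model format.
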