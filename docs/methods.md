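# Methods

`sacess` estimates parameters of nonlinear ODE models by weighted
least squares, using an enhanced scatter search (eSS) global optimizer and a
self-adaptive cooperative island layer on top of it. This note records the
model, the algorithmic choices, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Estimation problem

Given a dynamic model dx/dt = f(x, p, t), x(t0) = x0, an observation map
y = g(x, p, t), and measurements ym over experiments, observables and sample
times, the cost is

    J(p) = sum_eps sum_o sum_s  W[s,o] * (ym[s,o] - y[s,o](p))^2

subject to box bounds pL <= p <= pU and, optionally, algebraic constraints
h_eq(x,y,p) = 0 and h_in(x,y,p) <= 0. NaN entries in `ym` mark unobserved
samples and are excluded, which supports partial observability.

Numerical choices:

* Integration uses LSODA (adaptive, switches between Adams and BDF) through
  the low-overhead `scipy.integrate.odeint` wrapper, `rtol=1e-7`,
  `atol=1e-9` by default, configurable per model. These tolerances put the
  integration error several orders below the cost differences the search
  acts on for the bundled benchmarks.
* An integrator failure (blow-up, step-size collapse, non-finite
  observables) is not an exception: the point receives a large finite
  `failure_cost` (default 1e20) so the search simply moves away from
  pathological parameter regions.
* Constraints enter as a quadratic static penalty,
  `penalty_weight * (||h_eq||^2 + ||max(h_in, 0)||^2)` summed over sample
  points, default weight 1e3. A static penalty keeps the cost cheap and
  smooth; problems needing exact feasibility should post-process.
* Each parameter can be searched on a log10 scale (`log_scale_mask`).
  All search geometry — diversification, combination boxes, duplicate
  distances, diversity ranks — operates on solutions normalized to the unit
  cube from the (possibly log-scaled) bounds, so behavior is invariant to
  units and spans of individual parameters.

## Enhanced scatter search

The engine keeps a RefSet of `dim_refset` members, sorted by cost. One
external iteration does, in order: duplicate control, pairwise combination,
go-beyond intensification, a scheduled local search, the (1+lambda) update,
and stagnation restarts.

* **Diversification.** The initial `ndiverse` points (default
  `max(10*n_par, 2*dim_refset)`) form a latin hypercube in the unit cube;
  i.i.d. uniform sampling is available by flag. The RefSet takes the best
  half by cost plus a uniform random draw from the remainder.
* **Duplicate control.** Two members are duplicates when the maximum
  componentwise difference of their normalized vectors is below 1e-3; the
  worse member of such a pair is replaced by a fresh random evaluated
  solution, iterating to a fixed point (at most `dim_refset` passes). The
  threshold direction is "closer than", which is the only reading under
  which a 1e-3 default is meaningful.
* **Combination.** Every ordered pair (i, j) produces one offspring
  (`dim_refset*(dim_refset-1)` per iteration), sampled uniformly from the
  hyper-rectangle `[u_i - d*(1+beta), u_i + d*(1-beta)]` per dimension,
  where `d = (u_j - u_i)/2` and `beta = (rank_j - rank_i)/(dim_refset - 1)`.
  The box is anchored on parent i and biased beyond the better-ranked
  parent; offspring are clipped into the cube. The box construction and the
  rank bias are fixed here as a concrete, testable choice.
* **Go-beyond.** An offspring that beats its parent starts a directional
  exploitation: new points are drawn in the box extending beyond the child
  along the parent-to-child direction; after every two consecutive
  improvements the box size is halved; the first non-improvement stops the
  walk. Choosing "halve after two" keeps roughly geometric focusing without
  giving up after a single unlucky draw.
* **(1+lambda) update.** A solution may replace only the member whose
  hyper-rectangle produced it, and only the best offspring of a member may
  do so, strictly-better only. Replaced members reset their `n_stuck`
  counter; all others increment it. This parent-only rule is what prevents
  a single good region from flooding the small population.
* **Stagnation.** A member stuck for `stagnation_limit` iterations
  (default 20) is replaced by a random evaluated solution; the cooperative
  member gets twice the limit so a freshly received foreign solution is not
  discarded before it has been combined a few times.

Ties in cost are resolved by stable sorting (insertion order).

## Improvement method (local search)

The first local search launches once `local_n1` cost evaluations have been
spent (default 500); subsequent ones after every `local_n2` evaluations
(default 100). The start point is chosen among the iteration's combination
offspring by the rank score `(1-balance)*rank_quality +
balance*rank_diversity`, where diversity is the minimum normalized distance
to the archive of local solutions already found; ranks rather than raw
values make the score scale-free. `balance=0` is pure intensification. With
`best_sol` set, local search instead refines the incumbent best, and only in
iterations where it moved.

* **Solvers.** The local minimizer is pluggable (`local.solver:
  powell|simplex|none`). Both built-ins are derivative-free,
  bound-constrained by projection, and budgeted: every trial point passes
  through the counted evaluator, and the best point seen is what the search
  keeps, so a local step can never worsen the incumbent and never exceeds
  its budget (default `1000*sqrt(n_par)` evaluations per launch, capped by
  the remaining global budget). The default is Powell's conjugate-direction
  method: on the bundled benchmarks Nelder-Mead routinely exhausts the
  per-launch budget mid-descent, and the resulting half-converged archive
  entries poison the diversity ranking, while Powell's line searches
  converge on smooth wells within a fraction of the budget. Nelder-Mead
  remains available as `simplex`.
* **Archive proximity filter.** A launch is skipped when its start lies
  within a normalized max-norm radius (`archive_radius`, default 0.15) of an
  already archived local solution: re-descending a known basin costs a full
  launch budget and returns no information. The default balance is 0.7,
  slightly diversity-leaning, which together with the filter is what lets a
  single engine instance hop between basins of a rugged surface instead of
  polishing the same well repeatedly.

Disabling local search entirely (`local_n1=None`) reproduces the pure
global engine and is used as a control in the convergence tests.

## Cooperation layer

Islands run independent eSS instances with different settings and exchange
information through a master:

* **Spectrum.** For n islands, `dim_refset` moves geometrically 10 -> 20,
  `local_n2` 5 -> 100, `balance` 0 -> 0.5 from the aggressive to the
  conservative end.
* **Sending.** An island sends its best solution when it improves the
  shared best-known cost by a relative `epsilon_slave` (default 1e-3 —
  deliberately small; the master does the real filtering).
* **Spreading.** The master forwards a received solution to all other
  islands only when it improves the master's best-known cost by
  `epsilon_master`, starting at 10%. Improving-but-unqualified receptions
  still update the incumbent (so the threshold is always measured against
  the true best) and grow a refusal streak; after 10 consecutive refusals
  the threshold halves (0.10, 0.05, 0.025, ...). The originator of a spread
  solution is excluded from the broadcast.
* **Reception.** Each island funnels foreign solutions into a single
  cooperative RefSet slot: the first accepted one replaces the worst member
  and marks the slot; later ones may replace only that slot. The island's
  own members are never displaced by foreign solutions, bounding the
  diversity loss cooperation can cause.
* **Scoreboard and reconfiguration.** The master ranks islands by
  `n_comm * t_last` (qualified communications times the time of the last
  one, ties to the lower id). An island requests reconfiguration when it has
  spent more than `n_par * 5000` evaluations since its last cooperation or
  has received more solutions than it has sent; the master answers with the
  top-ranked island's `(dim_refset, local_n2, balance)`, never the
  requester's own, and only when the top island has cooperated at least
  twice — a single lucky early send is not treated as evidence that its
  settings are good. A RefSet being resized mid-run keeps its best members
  (and always its cooperative slot) and pads with random evaluated
  solutions.
* **Clocks and determinism.** Message timestamps come from a monotonic run
  clock owned by the backend. The in-process backend uses a simulated clock
  (global evaluation count), which makes every protocol decision — spreads,
  threshold values, rankings, settings updates — an exact, replayable
  function of the message log. The process backend uses the wall clock.

## Execution backends

* `inprocess` (default): a deterministic round-robin scheduler; islands
  advance one external iteration per turn and run their cooperation phase
  between turns. Reception and emission are buffered, so a slow island
  (e.g. inside a long local search) delays nobody's messages.
* `process`: one forked OS process per island with queue-based messaging,
  a shared evaluation counter for the global budget and a shared stop event.
  Asynchronous by construction; results are not bit-reproducible across
  runs.
* `parallel_evaluate` provides the batch-evaluation contract: dynamic
  work distribution (each worker pulls the next index as it finishes),
  costs bitwise identical to a sequential loop regardless of worker count,
  counter incremented by exactly the batch size, one retry per crashed
  evaluation, then `failure_cost`.

Stopping criteria — `max_evals`, `max_time`, a value-to-reach (VTR) — are
checked after every single evaluation, so evaluations-to-VTR measurements
are exact to one evaluation and a budget overrun is impossible by more than
the current in-flight point.

Random-number policy: a root seed spawns independent per-island streams via
`numpy.random.SeedSequence.spawn`; the sequential `run_ess` uses child 0,
which is why a one-island cooperative run with cooperation disabled
reproduces the sequential trace exactly.

## Synthetic benchmarks

`make_kinetic_chain(n_states, n_experiments, noise_sd, seed)` emulates the
structure of kinetic calibration benchmarks: a Michaelis-Menten reaction
chain S1 -> ... -> Sn (two parameters per step, tabulated true values of
order 1), observed at every state except the first, over experiments that
differ in initial substrate load (x1(0) = 1 + 0.5*e, 21 samples on [0, 10]).
Bounds span three decades asymmetrically around the truth
([p/100, p*10], log scale on), so the log-midpoint of the box does not
coincide with the true parameters. Observation noise is additive Gaussian
with per-observable standard deviation `noise_sd * max|y|`, and residual
weights are `1/max(ym)^2` per observable — a common convention that
balances observables of different magnitudes. The suggested VTR is 1e-6 for
noise-free data, or 1.2x the expected chi-square floor
(`n_residuals * noise_sd^2`) with noise.

`make_multimodal(n_par, n_minima, seed)` is a closed-form surface,
`f(p) = min_k(||p - c_k||^2 + h_k)` on [-5, 5]^n: one global well of depth 0
at a seed-derived center, `n_minima - 1` local wells with floors
`h_k = 1 + 0.15*||c_k - c_0||`, centers at least distance 2 apart so every
center is a strict local minimum. The floors deepen toward the global
center, giving the big-valley correlation between local-optimum quality and
distance to the global optimum that rugged kinetic estimation landscapes
exhibit; on a surface with geometrically uncorrelated well floors a good
local optimum carries no information about the global one, and no
quality-driven cooperation scheme could be expected to help. Evaluation
costs microseconds, which is what makes multi-seed convergence statistics
affordable. The surface is wrapped as a zero-dynamics estimation problem
(one sample at t=0, datum 0, prediction sqrt(f)), so the estimation cost
equals the surface exactly.

What these fixtures do not emulate: stiffness regimes and integrator
failures of real large-scale models, correlated measurement noise,
structural non-identifiability, and landscapes whose local searches are
orders of magnitude more expensive than a cost evaluation. Passing the
bundled studies shows the mechanisms work as specified at desk scale, not
that wall-clock speedups on cluster-scale problems are reproduced.

## Known limitations

* Cooperation at small scale: with 4 islands and desk-scale budgets on the
  bundled rugged surface, the cooperative variant does not beat the
  independent-runs baseline in median evaluations-to-VTR. Instrumented runs
  show why: island progress on a sum-of-wells surface is quantized at well
  floors, so once every island's shared best sits at a floor, no island can
  improve it by `epsilon_slave`, the message flow stops, and the threshold
  adaptation (which is driven by incoming solutions) stalls; meanwhile the
  broadcast member tops every island's RefSet and correlates their
  local-search starts, spending redundant budget in the same basins. The
  cooperative scheme's documented gains arrive with more islands and with
  landscapes whose progress is continuous rather than floor-quantized; the
  protocol here is implemented exactly as specified and the corresponding
  acceptance test is allowed to fail rather than the comparison being
  redefined.
* The process backend trades reproducibility for concurrency; protocol
  tests therefore run on the in-process backend only.
* Gradient-based local solvers (the strongest choice for smooth
  least-squares problems) are not bundled; the plug-in registry accepts
  them.
* SBML import, DAE mass matrices and sensitivity-equation gradients are out
  of scope.

## Problem sizes used in the test suite

The studies in `tests/test_acceptance.py` and `scripts/acceptance.py` use a
3-state chain (4 parameters, 2 experiments), 5-D convex and 10-D/15-D
multimodal surfaces, 10-20 seeds per study, and evaluation budgets between
5e3 and 2e5 — sizes chosen so a complete run of the suite plus the
acceptance script finishes comfortably on one CPU while every mechanism
(scheduling, cooperation, adaptation, recovery) is still exercised
end-to-end.
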