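"""Enhanced scatter search (eSS): the sequential global-search engine.

eSS maintains a small reference set (RefSet) of high-quality, mutually
distant solutions.  Each external iteration: (i) sorts the RefSet and
replaces near-duplicate members with fresh random solutions; (ii) combines
every ordered pair of members inside rank-biased hyper-rectangles;
(iii) intensifies improving offspring along the parent-to-child direction
("go-beyond"); (iv) optionally launches a scheduled local search;
(v) applies a (1+lambda)-style update in which an offspring may replace only
the member whose hyper-rectangle produced it, and only the best offspring of
that member may do so; (vi) restarts members stuck for too many iterations.

All geometric operations (combination boxes, duplicate distances, go-beyond
steps, diversification) work on solutions normalized to the unit cube from
the box bounds, so behavior is invariant to parameter scaling and honors
per-parameter log10 search spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from . import local as local_mod
from .problem import EstimationProblem
from .stopping import Stopper, StopSearch, StoppingCriteria

__all__ = [
    "Solution",
    "RefSet",
    "ESSSettings",
    "BestResult",
    "EssRun",
    "generate_diverse_set",
    "build_refset",
    "check_duplicates",
    "combination_box",
    "combine_pair",
    "go_beyond",
    "update_refset",
    "apply_stagnation",
    "run_ess",
]

ORIGINS = ("diverse", "combination", "go_beyond", "local", "foreign", "random_restart")


@dataclass
class Solution:
    """A parameter vector with its cost and search bookkeeping."""

    params: np.ndarray
    cost: float
    n_stuck: int = 0
    is_cooperative: bool = False
    origin: str = "diverse"

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    def copy(self) -> "Solution":
        return Solution(
            self.params.copy(), self.cost, self.n_stuck, self.is_cooperative, self.origin
        )


class RefSet:
    """A sorted, fixed-size reference population.

    Members are kept ascending by cost with a stable sort, so cost ties keep
    their insertion order.  At most one member may carry the cooperative
    flag (the slot reserved for solutions received from other islands).
    """

    def __init__(self, members: Sequence[Solution]):
        self.members: List[Solution] = list(members)
        self.sort()

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def sort(self) -> None:
        self.members.sort(key=lambda s: s.cost)

    @property
    def best(self) -> Solution:
        return self.members[0]

    @property
    def cooperative_index(self) -> Optional[int]:
        for k, s in enumerate(self.members):
            if s.is_cooperative:
                return k
        return None

    def validate(self) -> None:
        costs = [s.cost for s in self.members]
        assert costs == sorted(costs), "RefSet not sorted"
        assert sum(s.is_cooperative for s in self.members) <= 1, "multiple cooperative slots"


@dataclass
class ESSSettings:
    """Per-island strategy knobs.

    Small ``dim_refset`` / ``local_n2`` / ``balance`` give an aggressive
    (intensifying) search; large values a conservative (diversifying) one.
    ``local_n1``/``local_n2`` are in cost evaluations; ``local_n1=None``
    disables the improvement method.
    """

    dim_refset: int = 10
    ndiverse: Optional[int] = None  # None: max(10 * n_par, 2 * dim_refset)
    local_n1: Optional[float] = 500
    local_n2: float = 100
    balance: float = 0.7
    best_sol: bool = False
    duplicity_threshold: float = 1e-3
    stagnation_limit: int = 20
    cooperative_stagnation_factor: float = 2.0
    diversification: str = "lhs"  # or "uniform"
    local_solver: str = "powell"
    local_budget: Optional[int] = None  # None: 1000 * sqrt(n_par)
    # skip a local launch whose start is this close (normalized, max-norm)
    # to an already-archived local solution: re-descending a known basin
    # wastes the launch budget
    archive_radius: float = 0.05

    def __post_init__(self) -> None:
        if self.dim_refset < 4 or self.dim_refset % 2:
            raise ValueError("dim_refset must be >= 4 and even")
        if self.ndiverse is not None and self.ndiverse < self.dim_refset:
            raise ValueError("ndiverse must be >= dim_refset")
        if not 0.0 <= self.balance <= 1.0:
            raise ValueError("balance must lie in [0, 1]")
        if self.diversification not in ("lhs", "uniform"):
            raise ValueError("diversification must be 'lhs' or 'uniform'")

    def resolved_ndiverse(self, n_par: int) -> int:
        if self.ndiverse is not None:
            return self.ndiverse
        return max(10 * n_par, 2 * self.dim_refset)

    def resolved_local_budget(self, n_par: int) -> int:
        if self.local_budget is not None:
            return self.local_budget
        return local_mod.default_local_budget(n_par)


@dataclass
class BestResult:
    best: Solution
    total_evals: int
    n_iterations: int
    trace: List[dict]
    stop_reason: str


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _random_solution_params(problem: EstimationProblem, rng: np.random.Generator) -> np.ndarray:
    return problem.denormalize(rng.uniform(size=problem.n_par))


# -- diversification ---------------------------------------------------------


def generate_diverse_set(
    problem: EstimationProblem,
    n: int,
    rng,
    method: str = "lhs",
    evaluate: Optional[Callable] = None,
) -> List[Solution]:
    """Create and evaluate ``n`` space-filling solutions.

    Default is a latin-hypercube design in the normalized cube: each of the
    ``n`` equal bins per coordinate contains exactly one point.  ``uniform``
    draws i.i.d. points instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng)
    evaluate = evaluate if evaluate is not None else problem.evaluate_cost
    d = problem.n_par
    if method == "lhs":
        u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T + rng.uniform(size=(n, d))) / n
    elif method == "uniform":
        u = rng.uniform(size=(n, d))
    else:
        raise ValueError(f"unknown diversification method {method!r}")
    out = []
    for row in u:
        p = problem.denormalize(row)
        out.append(Solution(p, evaluate(p), origin="diverse"))
    return out


def build_refset(diverse: Sequence[Solution], settings: ESSSettings, rng=None) -> RefSet:
    """Half best-by-cost, half drawn uniformly from the remainder."""
    m = settings.dim_refset
    if len(diverse) < m:
        raise ValueError(f"need at least dim_refset={m} diverse solutions, got {len(diverse)}")
    rng = _as_rng(rng)
    order = sorted(range(len(diverse)), key=lambda k: (diverse[k].cost, k))
    n_best = m // 2
    chosen = [diverse[k] for k in order[:n_best]]
    rest = [diverse[k] for k in order[n_best:]]
    if len(diverse) == m:
        chosen += rest
    else:
        picks = rng.choice(len(rest), size=m - n_best, replace=False)
        chosen += [rest[k] for k in picks]
    return RefSet([s.copy() for s in chosen])


# -- duplicate control --------------------------------------------------------


def check_duplicates(
    refset: RefSet,
    problem: EstimationProblem,
    settings: ESSSettings,
    rng,
    evaluate: Optional[Callable] = None,
) -> RefSet:
    """Replace the worse member of any too-close pair with a random solution.

    Two members are too close when the maximum componentwise difference of
    their normalized vectors is below ``duplicity_threshold``.  Replacement
    repeats until no pair is too close (capped at dim_refset passes, since a
    fresh random duplicate is vanishingly unlikely but not impossible).
    """
    rng = _as_rng(rng)
    evaluate = evaluate if evaluate is not None else problem.evaluate_cost
    thr = settings.duplicity_threshold
    for _ in range(settings.dim_refset):
        refset.sort()
        u = np.array([problem.normalize(s.params) for s in refset.members])
        replaced = False
        for i in range(len(refset)):
            for j in range(i + 1, len(refset)):
                if np.max(np.abs(u[i] - u[j])) < thr:
                    p = _random_solution_params(problem, rng)
                    refset.members[j] = Solution(p, evaluate(p), origin="random_restart")
                    replaced = True
                    break
            if replaced:
                break
        if not replaced:
            break
    refset.sort()
    return refset


# -- combination --------------------------------------------------------------


def combination_box(u_i: np.ndarray, u_j: np.ndarray, beta: float):
    """Endpoints of the rank-biased combination hyper-rectangle.

    With ``delta = (u_j - u_i) / 2`` the box per dimension is
    ``[u_i - delta*(1+beta), u_i + delta*(1-beta)]``; positive ``beta``
    (parent i better ranked than parent j) shifts the box toward and beyond
    the better parent.
    """
    delta = (u_j - u_i) / 2.0
    return u_i - delta * (1.0 + beta), u_i + delta * (1.0 - beta)


def combine_pair(
    problem: EstimationProblem,
    parent_i: Solution,
    parent_j: Solution,
    rank_i: int,
    rank_j: int,
    dim_refset: int,
    rng,
) -> np.ndarray:
    """One offspring parameter vector for the ordered pair (i, j).

    The box is built in the normalized cube (so log-scaled parameters
    combine in log10 space) and the sample is clipped back into bounds.
    """
    rng = _as_rng(rng)
    u_i = problem.normalize(parent_i.params)
    u_j = problem.normalize(parent_j.params)
    beta = (rank_j - rank_i) / (dim_refset - 1)
    lo, hi = combination_box(u_i, u_j, beta)
    u = lo + rng.uniform(size=u_i.size) * (hi - lo)
    return problem.denormalize(np.clip(u, 0.0, 1.0))


# -- go-beyond ----------------------------------------------------------------


def go_beyond(
    parent: Solution,
    child: Solution,
    problem: EstimationProblem,
    rng,
    evaluate: Optional[Callable] = None,
) -> Solution:
    """Exploit the parent-to-child direction while improvement continues.

    If the child does not beat the parent it is returned untouched with no
    extra evaluations.  Otherwise new points are sampled in the box extending
    beyond the child along the improvement direction; after every two
    consecutive improvements the box size is halved, focusing the line
    search.  Stops at the first non-improvement.
    """
    if child.cost >= parent.cost:
        return child
    rng = _as_rng(rng)
    evaluate = evaluate if evaluate is not None else problem.evaluate_cost
    u_parent = problem.normalize(parent.params)
    u_child = problem.normalize(child.params)
    incumbent = child
    denom = 1.0
    improvements = 0
    while True:
        step = (u_child - u_parent) / denom
        u_new = np.clip(u_child + rng.uniform(size=u_child.size) * step, 0.0, 1.0)
        p_new = problem.denormalize(u_new)
        c_new = evaluate(p_new)
        if c_new < incumbent.cost:
            incumbent = Solution(p_new, c_new, origin="go_beyond")
            u_parent, u_child = u_child, u_new
            improvements += 1
            if improvements % 2 == 0:
                denom *= 2.0
        else:
            break
    return incumbent


# -- RefSet update and stagnation ----------------------------------------------


def update_refset(refset: RefSet, offspring_by_parent: Dict[int, List[Solution]]) -> RefSet:
    """(1+lambda) update: the best offspring of a slot replaces that slot only.

    A slot is replaced iff its best offspring is strictly better than the
    incumbent; replaced slots reset ``n_stuck`` to 0, all others increment it.
    The cooperative flag stays with the slot through replacement by its own
    offspring.  The RefSet is re-sorted afterwards.
    """
    n = len(refset)
    for idx in offspring_by_parent:
        if not 0 <= idx < n:
            raise ValueError(f"offspring references unknown RefSet slot {idx}")
    new_members = []
    for k, member in enumerate(refset.members):
        offspring = offspring_by_parent.get(k, [])
        if offspring:
            best_child = min(offspring, key=lambda s: s.cost)
            if best_child.cost < member.cost:
                incoming = best_child.copy()
                incoming.n_stuck = 0
                incoming.is_cooperative = member.is_cooperative
                new_members.append(incoming)
                continue
        member.n_stuck += 1
        new_members.append(member)
    refset.members = new_members
    refset.sort()
    return refset


def apply_stagnation(
    refset: RefSet,
    problem: EstimationProblem,
    settings: ESSSettings,
    rng,
    evaluate: Optional[Callable] = None,
) -> RefSet:
    """Restart members stuck past the stagnation limit with random solutions.

    The cooperative member gets a longer leash (limit multiplied by
    ``cooperative_stagnation_factor``) so that a recently received foreign
    solution is not discarded before it has had a chance to contribute; its
    flag is cleared if it is eventually restarted.
    """
    rng = _as_rng(rng)
    evaluate = evaluate if evaluate is not None else problem.evaluate_cost
    for k, member in enumerate(refset.members):
        limit = settings.stagnation_limit
        if member.is_cooperative:
            limit = limit * settings.cooperative_stagnation_factor
        if member.n_stuck >= limit:
            p = _random_solution_params(problem, rng)
            refset.members[k] = Solution(p, evaluate(p), origin="random_restart")
    refset.sort()
    return refset


# -- the engine ----------------------------------------------------------------


class Hooks:
    """Optional per-iteration callbacks; the cooperation layer plugs in here."""

    def after_init(self, run: "EssRun") -> None:  # pragma: no cover - default no-op
        pass

    def after_iteration(self, run: "EssRun") -> None:  # pragma: no cover - default no-op
        pass


class EssRun:
    """A stepwise eSS run over one problem with one settings vector.

    The island runner drives this class one external iteration at a time and
    interleaves cooperation phases between steps; :func:`run_ess` simply
    loops it until a stopping criterion fires.

    ``combine_enabled`` / ``go_beyond_enabled`` exist for ablation baselines
    (pure random-restart search) and stay on in normal use.
    """

    def __init__(
        self,
        problem: EstimationProblem,
        settings: ESSSettings,
        rng,
        stopper: Stopper,
        hooks: Optional[Hooks] = None,
        island_id: int = 0,
        batch_evaluator: Optional[Callable] = None,
        combine_enabled: bool = True,
        go_beyond_enabled: bool = True,
    ):
        self.problem = problem
        self.settings = settings
        self.rng = _as_rng(rng)
        self.stopper = stopper
        self.hooks = hooks or Hooks()
        self.island_id = island_id
        self.batch_evaluator = batch_evaluator
        self.combine_enabled = combine_enabled
        self.go_beyond_enabled = go_beyond_enabled

        self.refset: Optional[RefSet] = None
        self.best: Optional[Solution] = None
        self.iteration = 0
        self.own_evals = 0  # evaluations performed by this run alone
        self.trace: List[dict] = []
        self.sched = local_mod.LocalScheduleState()
        self.stop_reason = "running"
        self.last_offspring: Dict[int, List[Solution]] = {}
        self.best_updated_this_iteration = False

    # counting evaluator: updates incumbent best, then checks stopping
    def evaluate(self, p: np.ndarray) -> float:
        cost = self.problem.evaluate_cost(p)
        self.own_evals += 1
        if self.best is None or cost < self.best.cost:
            self.best = Solution(np.array(p, float), cost, origin="combination")
            self.best_updated_this_iteration = True
        self.stopper.check(self.best.cost)
        return cost

    @property
    def evals_used(self) -> int:
        return self.own_evals

    def _trace_row(self, event: str) -> None:
        self.trace.append(
            {
                "iteration": self.iteration,
                "evals": self.problem.n_evals,
                "best_cost": self.best.cost if self.best is not None else math.inf,
                "event": event,
                "island": self.island_id,
            }
        )

    def initialize(self) -> None:
        s = self.settings
        diverse = generate_diverse_set(
            self.problem,
            s.resolved_ndiverse(self.problem.n_par),
            self.rng,
            method=s.diversification,
            evaluate=self.evaluate,
        )
        self.refset = build_refset(diverse, s, self.rng)
        self._trace_row("init")
        self.hooks.after_init(self)
        self.stopper.check(self.best.cost)

    def step(self) -> None:
        """One external iteration of Algorithm-style eSS."""
        s = self.settings
        self.best_updated_this_iteration = False
        self.refset.sort()
        check_duplicates(self.refset, self.problem, s, self.rng, self.evaluate)

        offspring_by_parent: Dict[int, List[Solution]] = {}
        if self.combine_enabled:
            members = [m.copy() for m in self.refset.members]
            pending = []  # (parent_slot, params)
            n = len(members)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    params = combine_pair(self.problem, members[i], members[j], i, j, n, self.rng)
                    pending.append((i, params))
            if self.batch_evaluator is not None:
                costs = self.batch_evaluator([p for _, p in pending])
                self.own_evals += len(costs)
                for (i, params), cost in zip(pending, costs):
                    if self.best is None or cost < self.best.cost:
                        self.best = Solution(np.array(params), cost, origin="combination")
                        self.best_updated_this_iteration = True
                    sol = Solution(params, cost, origin="combination")
                    offspring_by_parent.setdefault(i, []).append(sol)
                self.stopper.check(self.best.cost)
            else:
                for i, params in pending:
                    sol = Solution(params, self.evaluate(params), origin="combination")
                    offspring_by_parent.setdefault(i, []).append(sol)

            if self.go_beyond_enabled:
                for i, lst in offspring_by_parent.items():
                    parent = members[i]
                    for k, child in enumerate(lst):
                        if child.cost < parent.cost:
                            lst[k] = go_beyond(parent, child, self.problem, self.rng, self.evaluate)

        self._local_phase(offspring_by_parent)

        self.last_offspring = {k: [s.copy() for s in v] for k, v in offspring_by_parent.items()}
        update_refset(self.refset, offspring_by_parent)
        apply_stagnation(self.refset, self.problem, s, self.rng, self.evaluate)
        self.iteration += 1
        self._trace_row("iterate")
        self.hooks.after_iteration(self)
        self.stopper.check(self.best.cost)

    def _local_phase(self, offspring_by_parent: Dict[int, List[Solution]]) -> None:
        s = self.settings
        if s.local_solver == "none":
            return
        if not local_mod.should_launch_local(self.problem.n_evals, self.sched, s):
            return
        candidates = [sol for lst in offspring_by_parent.values() for sol in lst]
        if s.best_sol:
            # refine only the best found solution, and only when it moved
            if not self.best_updated_this_iteration:
                return
            start = self.best.copy()
        elif not self.sched.first_done or not candidates:
            start = self.best.copy()
        else:
            candidates = self._filter_near_archive(candidates) or candidates
            start = local_mod.select_local_start(
                candidates, self.sched.local_solutions, s.balance, self.problem
            )
        if self.sched.local_solutions and self._near_archive(start):
            return  # known basin; try again next iteration with new offspring
        budget = s.resolved_local_budget(self.problem.n_par)
        remaining = self.stopper.remaining_evals()
        if math.isfinite(remaining):
            budget = int(min(budget, max(remaining, 0)))
        if budget <= 0:
            return
        refined = local_mod.local_search(
            start, self.problem, budget, evaluate=self.evaluate, solver=s.local_solver
        )
        self.sched.first_done = True
        self.sched.evals_at_last_local = self.problem.n_evals
        self.sched.local_solutions.append(refined.copy())
        # the refined point competes for the slot of the current best member
        offspring_by_parent.setdefault(0, []).append(refined)
        self._trace_row("local")

    def _near_archive(self, sol: Solution) -> bool:
        u = self.problem.normalize(sol.params)
        for arch in self.sched.local_solutions:
            if np.max(np.abs(u - self.problem.normalize(arch.params))) < self.settings.archive_radius:
                return True
        return False

    def _filter_near_archive(self, candidates):
        return [c for c in candidates if not self._near_archive(c)]

    def finalize(self, reason: str) -> BestResult:
        self.stop_reason = reason
        self._trace_row("stop")
        return BestResult(
            best=self.best.copy() if self.best is not None else None,
            total_evals=self.evals_used,
            n_iterations=self.iteration,
            trace=self.trace,
            stop_reason=reason,
        )

    def run(self) -> BestResult:
        try:
            self.initialize()
            while True:
                self.step()
        except StopSearch as stop:
            return self.finalize(stop.reason)


def run_ess(
    problem: EstimationProblem,
    settings: ESSSettings,
    stopping: StoppingCriteria,
    rng,
    hooks: Optional[Hooks] = None,
) -> BestResult:
    """Run sequential eSS until a stopping criterion fires.

    ``rng`` may be a seed or a Generator; an integer seed reproduces the
    exact trace of a one-island cooperative run with cooperation disabled.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence(int(rng)).spawn(1)[0])
    stopper = Stopper(stopping, problem)
    return EssRun(problem, settings, rng, stopper, hooks=hooks).run()
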