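"""The improvement method: scheduled local refinement of promising solutions.

Scatter search owes much of its efficiency on smooth landscapes to periodic
local searches launched from selected solutions.  The schedule has two knobs:
the first search happens once ``local_n1`` cost evaluations have been spent,
and subsequent ones after every further ``local_n2`` evaluations.  The start
point balances quality (low cost) against diversity (distance from all
previously found local optima) through the ``balance`` weight in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
from scipy.optimize import Bounds, minimize

__all__ = [
    "LocalScheduleState",
    "should_launch_local",
    "select_local_start",
    "local_search",
    "default_local_budget",
    "LOCAL_SOLVERS",
    "register_local_solver",
]


@dataclass
class LocalScheduleState:
    """Bookkeeping for the local-search schedule and the archive of optima."""

    evals_at_last_local: int = 0
    first_done: bool = False
    local_solutions: List = field(default_factory=list)


def should_launch_local(total_evals: int, sched: LocalScheduleState, settings) -> bool:
    """True when the evaluation schedule calls for a local search.

    The first search launches once ``local_n1`` evaluations have been spent;
    later ones after ``local_n2`` evaluations since the previous launch.
    ``local_n1`` of None or infinity disables local search entirely.
    """
    n1 = settings.local_n1
    if n1 is None or (isinstance(n1, float) and math.isinf(n1)):
        return False
    if not sched.first_done:
        return total_evals >= n1
    return total_evals - sched.evals_at_last_local >= settings.local_n2


def select_local_start(candidates, archive, balance: float, problem):
    """Pick the start point among this iteration's combination solutions.

    Each candidate is scored ``(1-balance)*rank_quality + balance*rank_diversity``
    where quality ranks ascending cost and diversity ranks descending minimum
    normalized distance to the archived local solutions; the lowest combined
    score wins.  With an empty archive only quality counts.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    order_q = sorted(range(len(candidates)), key=lambda k: (candidates[k].cost, k))
    rank_q = np.empty(len(candidates))
    rank_q[order_q] = np.arange(len(candidates))
    if not archive or balance == 0.0:
        return candidates[order_q[0]]
    arch_u = np.array([problem.normalize(s.params) for s in archive])
    dists = np.array(
        [
            float(np.min(np.linalg.norm(arch_u - problem.normalize(c.params), axis=1)))
            for c in candidates
        ]
    )
    order_d = sorted(range(len(candidates)), key=lambda k: (-dists[k], k))
    rank_d = np.empty(len(candidates))
    rank_d[order_d] = np.arange(len(candidates))
    score = (1.0 - balance) * rank_q + balance * rank_d
    best = min(range(len(candidates)), key=lambda k: (score[k], candidates[k].cost, k))
    return candidates[best]


def default_local_budget(n_par: int) -> int:
    """Per-launch evaluation budget; grows with the square root of dimension."""
    return int(1000 * math.sqrt(n_par))


def _simplex_solver(start_params, cost_fn, lower, upper, budget):
    """Bound-constrained Nelder-Mead with projection onto the box."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)

    def fun(p):
        return cost_fn(np.clip(p, lower, upper))

    minimize(
        fun,
        np.asarray(start_params, float),
        method="Nelder-Mead",
        bounds=Bounds(lower, upper),
        options={"maxfev": int(budget), "xatol": 1e-10, "fatol": 1e-12},
    )


def _powell_solver(start_params, cost_fn, lower, upper, budget):
    """Powell's conjugate-direction method: exact on quadratics, no gradients."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)

    def fun(p):
        return cost_fn(np.clip(p, lower, upper))

    minimize(
        fun,
        np.asarray(start_params, float),
        method="Powell",
        bounds=Bounds(lower, upper),
        options={"maxfev": int(budget), "xtol": 1e-10, "ftol": 1e-12},
    )


def _null_solver(start_params, cost_fn, lower, upper, budget):
    return None


LOCAL_SOLVERS = {
    "simplex": _simplex_solver,
    "powell": _powell_solver,
    "none": _null_solver,
}


def register_local_solver(name: str, solver: Callable) -> None:
    """Plug in a local minimizer.

    A solver is called as ``solver(start_params, cost_fn, lower, upper,
    budget)``; every point it wants evaluated must go through ``cost_fn``
    (which counts evaluations and tracks the best point), and it should stop
    after ``budget`` evaluations.  Its return value is ignored — the best
    point seen by ``cost_fn`` is what the search keeps.
    """
    LOCAL_SOLVERS[name] = solver


def local_search(
    start,
    problem,
    budget: int,
    evaluate: Optional[Callable[[np.ndarray], float]] = None,
    solver: str = "simplex",
):
    """Refine ``start`` with a budgeted local minimizer; never worsens it.

    Returns a new solution with ``cost <= start.cost`` whose parameters lie
    within bounds.  All evaluations are counted (through ``evaluate`` when
    given, else the problem's counting evaluator).  A non-positive budget
    returns ``start`` unchanged.
    """
    from .ess import Solution  # local import to avoid a cycle

    if budget <= 0:
        return start
    evaluate = evaluate if evaluate is not None else problem.evaluate_cost
    best_p = np.array(start.params, dtype=float)
    best_c = start.cost
    used = 0

    def cost_fn(p):
        nonlocal best_p, best_c, used
        if used >= budget:
            # soft cutoff for solvers that overshoot maxfev slightly
            return best_c + abs(best_c) + 1.0
        p = problem.clip(p)
        c = evaluate(p)
        used += 1
        if c < best_c:
            best_c = c
            best_p = p.copy()
        return c

    LOCAL_SOLVERS[solver](best_p.copy(), cost_fn, problem.lower, problem.upper, budget)
    return Solution(params=best_p, cost=best_c, origin="local")
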