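"""Running cooperative (and independent) multi-island searches.

Two execution backends sit behind one contract:

* ``inprocess`` — a deterministic round-robin scheduler with a simulated
  clock (message timestamps measured in global cost evaluations).  Every
  protocol decision is exactly reproducible, which is what all protocol
  tests run against.
* ``process`` — one OS process per island with real message queues, for
  actual wall-clock speedups.  Falls back to ``inprocess`` with a warning
  when process support is unavailable.

The fine-grained layer, :func:`parallel_evaluate`, evaluates a batch of
parameter vectors with dynamic work distribution and guarantees bitwise the
same costs as a sequential loop, regardless of worker count.
"""

from __future__ import annotations

import csv
import json
import time
import warnings
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, ThreadPoolExecutor, wait
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from . import coop as coop_mod
from .ess import ESSSettings, EssRun, Solution
from .problem import BoundsError, EstimationProblem
from .stopping import Stopper, StopSearch, StoppingCriteria

__all__ = [
    "RunResult",
    "make_island_settings",
    "parallel_evaluate",
    "run_sacess",
    "run_np_ess",
    "replay_master",
    "write_trace_csv",
    "write_result_json",
]


@dataclass
class RunResult:
    best: Solution
    total_evals: int
    wall_time: float
    traces: List[List[dict]]
    message_log: List[coop_mod.CooperationMessage]
    stop_reason: str
    master: Optional[coop_mod.MasterState] = None
    island_results: List = field(default_factory=list)

    @property
    def trace(self) -> List[dict]:
        """Flat trace over all islands, ordered by evaluation count."""
        rows = [r for t in self.traces for r in t]
        rows.sort(key=lambda r: r["evals"])
        return rows


# -- settings spectrum --------------------------------------------------------


def _round_even(x: float) -> int:
    return max(4, int(round(x / 2.0)) * 2)


def make_island_settings(
    n_islands: int, problem: EstimationProblem, base: Optional[ESSSettings] = None
) -> List[ESSSettings]:
    """A deterministic aggressive-to-conservative spectrum over islands.

    Island 0 is the most aggressive (RefSet of 10, local searches every 5
    evaluations, pure quality start selection); the last island the most
    conservative (RefSet of 20, local searches every 100 evaluations,
    balance 0.5).  Intermediate islands interpolate geometrically.
    """
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    base = base if base is not None else ESSSettings()
    if n_islands == 1:
        return [base]
    out = []
    for i in range(n_islands):
        f = i / (n_islands - 1)
        out.append(
            replace(
                base,
                dim_refset=_round_even(10.0 * 2.0**f),
                local_n2=int(round(5.0 * 20.0**f)),
                balance=0.5 * f,
            )
        )
    return out


# -- fine-grained parallel evaluation -------------------------------------------


def _eval_one(problem: EstimationProblem, p) -> float:
    try:
        return problem.cost_only(p)
    except BoundsError:
        raise
    except Exception:
        # single retry, then give up on this vector
        try:
            return problem.cost_only(p)
        except BoundsError:
            raise
        except Exception:
            return float(problem.failure_cost)


def parallel_evaluate(
    solutions: Sequence[np.ndarray],
    problem: EstimationProblem,
    workers: int = 1,
    mode: str = "thread",
) -> List[float]:
    """Evaluate a batch of parameter vectors; result independent of workers.

    Work is distributed dynamically — each worker pulls the next unevaluated
    index as it finishes — and the costs returned are identical, element by
    element, to a sequential loop.  The problem's evaluation counter is
    incremented by exactly ``len(solutions)``.  A crashed evaluation is
    retried once and then charged ``failure_cost``.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    solutions = list(solutions)
    if workers == 1:
        costs = [_eval_one(problem, p) for p in solutions]
        problem.n_evals += len(solutions)
        return costs
    pool_cls = ThreadPoolExecutor if mode == "thread" else ProcessPoolExecutor
    costs: List[Optional[float]] = [None] * len(solutions)
    with pool_cls(max_workers=workers) as pool:
        pending = {}
        it = iter(range(len(solutions)))
        # prime one task per worker, then hand out indices as workers free up
        for _ in range(workers):
            k = next(it, None)
            if k is None:
                break
            pending[pool.submit(_eval_one, problem, solutions[k])] = k
        while pending:
            done, _ = wait(pending, return_when=FIRST_COMPLETED)
            for fut in done:
                k = pending.pop(fut)
                costs[k] = fut.result()
                nxt = next(it, None)
                if nxt is not None:
                    pending[pool.submit(_eval_one, problem, solutions[nxt])] = nxt
    problem.n_evals += len(solutions)
    return costs


# -- the in-process cooperative scheduler ----------------------------------------


class _SimulatedClock:
    """Run time measured in global cost evaluations — fully deterministic."""

    def __init__(self, problem: EstimationProblem):
        self.problem = problem

    def time(self) -> float:
        return float(self.problem.n_evals)


def _apply_settings_update(run: EssRun, payload: ESSSettings) -> None:
    """Adopt the adaptive knobs (dim_refset, local_n2, balance) mid-run."""
    run.settings = replace(
        run.settings,
        dim_refset=payload.dim_refset,
        local_n2=payload.local_n2,
        balance=payload.balance,
        ndiverse=None,
    )
    refset = run.refset
    refset.sort()
    target = payload.dim_refset
    if len(refset) > target:
        keep = refset.members[:target]
        # never drop the cooperative slot during a resize
        coop_idx = refset.cooperative_index
        if coop_idx is not None and coop_idx >= target:
            keep[-1] = refset.members[coop_idx]
        refset.members = keep
    while len(refset.members) < target:
        p = run.problem.denormalize(run.rng.uniform(size=run.problem.n_par))
        refset.members.append(Solution(p, run.evaluate(p), origin="random_restart"))
    refset.sort()


def run_sacess(
    problem: EstimationProblem,
    n_islands: int,
    stopping: StoppingCriteria,
    seed: int,
    backend: str = "inprocess",
    base_settings: Optional[ESSSettings] = None,
    cooperate: bool = True,
    epsilon_slave: float = coop_mod.DEFAULT_SLAVE_EPSILON,
    refusal_window: int = coop_mod.DEFAULT_REFUSAL_WINDOW,
    workers: int = 1,
) -> RunResult:
    """Run the self-adaptive cooperative search: master + ``n_islands`` islands.

    Islands never block on communication: emission and reception are
    buffered, and an island that misses a message simply drains it at its
    next cooperation phase.  Stops as soon as any stopping criterion fires
    anywhere and returns the best global solution with full logs.
    """
    if backend == "process":
        try:
            from .procbackend import run_sacess_processes

            return run_sacess_processes(
                problem,
                n_islands,
                stopping,
                seed,
                base_settings=base_settings,
                cooperate=cooperate,
                epsilon_slave=epsilon_slave,
                refusal_window=refusal_window,
            )
        except (ImportError, OSError) as err:  # pragma: no cover - platform dependent
            warnings.warn(f"process backend unavailable ({err}); using in-process scheduler")
    elif backend != "inprocess":
        raise ValueError(f"unknown backend {backend!r}")

    t_start = time.monotonic()
    settings_list = make_island_settings(n_islands, problem, base_settings)
    children = np.random.SeedSequence(int(seed)).spawn(n_islands)
    clock = _SimulatedClock(problem)
    stopper = Stopper(stopping, problem)

    runs = [
        EssRun(
            problem,
            settings_list[i],
            np.random.default_rng(children[i]),
            stopper,
            island_id=i,
            batch_evaluator=(
                (lambda sols: parallel_evaluate(sols, problem, workers)) if workers > 1 else None
            ),
        )
        for i in range(n_islands)
    ]
    islands = [coop_mod.IslandState(island_id=i, settings=settings_list[i]) for i in range(n_islands)]
    master = coop_mod.MasterState()
    for i in range(n_islands):
        master.register_island(i, settings_list[i])
    message_log: List[coop_mod.CooperationMessage] = []
    prev_evals = [0] * n_islands

    stop_reason = "running"
    try:
        for run in runs:
            run.initialize()
        while True:
            for i, run in enumerate(runs):
                run.step()
                if cooperate:
                    _cooperation_phase(
                        i, run, islands[i], master, runs, islands, clock, message_log,
                        epsilon_slave, refusal_window, prev_evals,
                    )
    except StopSearch as stop:
        stop_reason = stop.reason

    island_results = [r.finalize(stop_reason) for r in runs]
    bests = [r.best for r in island_results if r.best is not None]
    best = min(bests, key=lambda s: s.cost).copy() if bests else None
    return RunResult(
        best=best,
        total_evals=problem.n_evals,
        wall_time=time.monotonic() - t_start,
        traces=[r.trace for r in island_results],
        message_log=message_log,
        stop_reason=stop_reason,
        master=master,
        island_results=island_results,
    )


def _cooperation_phase(
    i: int,
    run: EssRun,
    island: coop_mod.IslandState,
    master: coop_mod.MasterState,
    runs: List[EssRun],
    islands: List[coop_mod.IslandState],
    clock: _SimulatedClock,
    message_log: List[coop_mod.CooperationMessage],
    epsilon_slave: float,
    refusal_window: int,
    prev_evals: List[int],
) -> None:
    """One island's per-iteration cooperation: receive, send, adapt."""
    now = clock.time()
    island.evals_since_coop += run.evals_used - prev_evals[i]
    prev_evals[i] = run.evals_used

    # reception: drain pending foreign solutions into the cooperative slot.
    # best_known (the shared cooperation gate) absorbs the broadcast, but the
    # island's own best-found bookkeeping is left alone: its search schedule
    # keeps refining its own discoveries, and the foreign solution competes
    # through the RefSet like any other member.
    coop_mod.slave_receive_phase(island, run.refset)

    # emission: report a sufficiently improved best to the master
    msg = coop_mod.slave_send_phase(
        island, epsilon_slave, current_best=run.best, send_time=now
    )
    if msg is not None:
        island.evals_since_coop = 0
        message_log.append(msg)
        master, spread = coop_mod.master_handle_solution(master, msg)
        coop_mod.adapt_threshold(master, refusal_window)
        if spread is not None:
            for j, other in enumerate(islands):
                if j == i:
                    continue  # the originator is excluded from the broadcast
                other.inbox.append(
                    coop_mod.CooperationMessage(
                        kind="solution",
                        sender=-1,
                        payload=spread.copy(),
                        send_time=now,
                        recipient=j,
                    )
                )

    # adaptation: a stalling island asks the master for better settings
    if coop_mod.reconfiguration_check(island, run.problem.n_par, send_time=now):
        request = island.outbox.pop()
        message_log.append(request)
        update = coop_mod.master_handle_reconfig(master, request)
        message_log.append(update)
        if update.payload is not None:
            _apply_settings_update(run, update.payload)
            island.settings = run.settings
            master.scoreboard[i].settings = run.settings


def run_np_ess(
    problem: EstimationProblem,
    n_runs: int,
    stopping: StoppingCriteria,
    seed: int,
    base_settings: Optional[ESSSettings] = None,
) -> RunResult:
    """Independent parallel eSS runs (no cooperation): the comparison baseline.

    Uses the same settings spectrum and interleaved scheduling as the
    cooperative variant, with disjoint RNG streams and an empty message log;
    reports the best run's result.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return run_sacess(
        problem,
        n_runs,
        stopping,
        seed,
        backend="inprocess",
        base_settings=base_settings,
        cooperate=False,
    )


# -- protocol replay -------------------------------------------------------------


def replay_master(
    messages: Sequence[coop_mod.CooperationMessage],
    refusal_window: int = coop_mod.DEFAULT_REFUSAL_WINDOW,
    island_ids: Optional[Sequence[int]] = None,
) -> dict:
    """Re-run the master's decisions over a timestamped message log.

    Returns the spread decision per solution message, the threshold value
    after each message, and the final scoreboard ranking.  Because the
    master is a pure function of the log, replaying is byte-identical across
    runs — the basis of the protocol-exactness tests and ``sacess replay``.
    """
    ms = coop_mod.MasterState()
    ids = set(island_ids or [])
    for m in messages:
        if m.sender >= 0:
            ids.add(m.sender)
    for i in sorted(ids):
        ms.register_island(i)
    spreads: List[bool] = []
    thresholds: List[float] = []
    for m in messages:
        if m.kind == "solution" and m.sender >= 0:
            ms, spread = coop_mod.master_handle_solution(ms, m)
            coop_mod.adapt_threshold(ms, refusal_window)
            spreads.append(spread is not None)
            thresholds.append(ms.epsilon_master)
    return {
        "spreads": spreads,
        "thresholds": thresholds,
        "ranking": coop_mod.rank_islands(ms),
        "scoreboard": {
            i: {"n_comm": r.n_comm, "t_last": r.t_last, "score": r.score}
            for i, r in ms.scoreboard.items()
        },
        "final_epsilon": ms.epsilon_master,
        "best_cost": ms.best_known.cost if ms.best_known is not None else None,
    }


# -- output writers ---------------------------------------------------------------


def write_trace_csv(result: RunResult, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["iteration", "evals", "best_cost", "event", "island"])
        w.writeheader()
        for row in result.trace:
            w.writerow(row)


def write_result_json(result: RunResult, path) -> None:
    payload = {
        "best_params": result.best.params.tolist() if result.best is not None else None,
        "best_cost": result.best.cost if result.best is not None else None,
        "total_evals": result.total_evals,
        "wall_time": result.wall_time,
        "stop_reason": result.stop_reason,
        "n_messages": len(result.message_log),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
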