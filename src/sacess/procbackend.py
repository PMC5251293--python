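"""Process-based island backend: one OS process per island, queue messaging.

The in-process scheduler interleaves islands deterministically; this backend
trades that determinism for genuine concurrency.  Each island runs its eSS
in a forked process, exchanging cooperation messages with the master (the
parent process) through multiprocessing queues.  Emission and reception are
both non-blocking: an island drains whatever has arrived at its next
cooperation phase and never waits.

The global evaluation budget is enforced through a shared counter; VTR and
time limits fire in whichever process observes them first, and a shared stop
event halts everyone else at their next evaluation.
"""

from __future__ import annotations

import queue as queue_mod
import time
from typing import List, Optional

import numpy as np

from . import coop as coop_mod
from .ess import ESSSettings, EssRun, Hooks
from .stopping import Stopper, StopSearch, StoppingCriteria


class _GlobalCounterView:
    """Presents the shared evaluation counter as a problem-like object."""

    def __init__(self, counter):
        self._counter = counter

    @property
    def n_evals(self) -> int:
        return int(self._counter.value)


class _CoopHooks(Hooks):
    """Per-iteration cooperation for an island process."""

    def __init__(self, island_state, inbox, to_master, epsilon_slave, t0):
        self.island = island_state
        self.inbox = inbox
        self.to_master = to_master
        self.epsilon_slave = epsilon_slave
        self.t0 = t0
        self.prev_evals = 0

    def _now(self) -> float:
        return time.monotonic() - self.t0

    def after_iteration(self, run: EssRun) -> None:
        island = self.island
        island.evals_since_coop += run.evals_used - self.prev_evals
        self.prev_evals = run.evals_used
        # drain whatever the master has sent so far (never block)
        while True:
            try:
                msg = self.inbox.get_nowait()
            except queue_mod.Empty:
                break
            if msg.kind == "settings_update":
                if msg.payload is not None:
                    from .orchestrate import _apply_settings_update

                    _apply_settings_update(run, msg.payload)
                    island.settings = run.settings
                continue
            island.inbox.append(msg)
        coop_mod.slave_receive_phase(island, run.refset)
        msg = coop_mod.slave_send_phase(
            island, self.epsilon_slave, current_best=run.best, send_time=self._now()
        )
        if msg is not None:
            island.evals_since_coop = 0
            self.to_master.put(msg)
        if coop_mod.reconfiguration_check(island, run.problem.n_par, send_time=self._now()):
            self.to_master.put(island.outbox.pop())


def _island_worker(
    problem,
    settings: ESSSettings,
    seed_entropy,
    stopping: StoppingCriteria,
    island_id: int,
    to_master,
    inbox,
    stop_event,
    counter,
    cooperate: bool,
    epsilon_slave: float,
    t0: float,
) -> None:
    base_eval = problem.evaluate_cost

    def counting_eval(p):
        cost = base_eval(p)
        with counter.get_lock():
            counter.value += 1
        if stop_event.is_set():
            raise StopSearch("remote")
        return cost

    problem.evaluate_cost = counting_eval
    stopper = Stopper(stopping, _GlobalCounterView(counter))
    island_state = coop_mod.IslandState(island_id=island_id, settings=settings)
    hooks = (
        _CoopHooks(island_state, inbox, to_master, epsilon_slave, t0) if cooperate else Hooks()
    )
    run = EssRun(
        problem,
        settings,
        np.random.default_rng(seed_entropy),
        stopper,
        hooks=hooks,
        island_id=island_id,
    )
    result = run.run()
    stop_event.set()
    to_master.put(("result", island_id, result))


def run_sacess_processes(
    problem,
    n_islands: int,
    stopping: StoppingCriteria,
    seed: int,
    base_settings: Optional[ESSSettings] = None,
    cooperate: bool = True,
    epsilon_slave: float = coop_mod.DEFAULT_SLAVE_EPSILON,
    refusal_window: int = coop_mod.DEFAULT_REFUSAL_WINDOW,
):
    import multiprocessing as mp

    from .orchestrate import RunResult, make_island_settings

    ctx = mp.get_context("fork")
    t_start = time.monotonic()
    settings_list = make_island_settings(n_islands, problem, base_settings)
    children = np.random.SeedSequence(int(seed)).spawn(n_islands)

    to_master = ctx.Queue()
    inboxes = [ctx.Queue() for _ in range(n_islands)]
    stop_event = ctx.Event()
    counter = ctx.Value("q", 0)

    procs = [
        ctx.Process(
            target=_island_worker,
            args=(
                problem,
                settings_list[i],
                children[i],
                stopping,
                i,
                to_master,
                inboxes[i],
                stop_event,
                counter,
                cooperate,
                epsilon_slave,
                t_start,
            ),
        )
        for i in range(n_islands)
    ]
    for p in procs:
        p.start()

    master = coop_mod.MasterState()
    for i in range(n_islands):
        master.register_island(i, settings_list[i])
    message_log: List[coop_mod.CooperationMessage] = []
    results = {}
    deadline = None if stopping.max_time is None else t_start + stopping.max_time

    while len(results) < n_islands:
        if deadline is not None and time.monotonic() > deadline:
            stop_event.set()
        try:
            item = to_master.get(timeout=0.05)
        except queue_mod.Empty:
            if stop_event.is_set() and not any(p.is_alive() for p in procs):
                break
            continue
        if isinstance(item, tuple) and item[0] == "result":
            results[item[1]] = item[2]
            continue
        msg: coop_mod.CooperationMessage = item
        message_log.append(msg)
        if msg.kind == "solution":
            master, spread = coop_mod.master_handle_solution(master, msg)
            coop_mod.adapt_threshold(master, refusal_window)
            if spread is not None:
                for j in range(n_islands):
                    if j != msg.sender:
                        inboxes[j].put(
                            coop_mod.CooperationMessage(
                                kind="solution",
                                sender=-1,
                                payload=spread.copy(),
                                send_time=msg.send_time,
                                recipient=j,
                            )
                        )
        elif msg.kind == "reconfig_request":
            update = coop_mod.master_handle_reconfig(master, msg)
            message_log.append(update)
            inboxes[msg.recipient if msg.recipient is not None else msg.sender].put(update)

    stop_event.set()
    for p in procs:
        p.join(timeout=10)
        if p.is_alive():  # pragma: no cover - defensive
            p.terminate()

    island_results = [results[i] for i in sorted(results)]
    bests = [r.best for r in island_results if r.best is not None]
    best = min(bests, key=lambda s: s.cost).copy() if bests else None
    stop_reason = island_results[0].stop_reason if island_results else "no_results"
    return RunResult(
        best=best,
        total_evals=int(counter.value),
        wall_time=time.monotonic() - t_start,
        traces=[r.trace for r in island_results],
        message_log=message_log,
        stop_reason=stop_reason,
        master=master,
        island_results=island_results,
    )
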