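"""Self-adaptive cooperation between scatter-search islands.

A master process coordinates islands running independent eSS searches.
Islands send solutions that improve their view of the best-known cost by a
small relative epsilon; the master spreads a received solution to the other
islands only when it improves the global best-known cost by at least a
larger threshold (initially 10%), halving that threshold whenever too many
improving-but-unqualified solutions pile up.  The master also keeps a
scoreboard ranking islands by ``n_comm * t_last`` (number of qualified
communications times the time of the last one); islands that detect they are
stalling request a reconfiguration and receive the settings of the
top-ranked island.

Everything here is a pure function of (state, message), which makes the
protocol exactly replayable from a timestamped message log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ess import ESSSettings, RefSet, Solution

__all__ = [
    "CooperationMessage",
    "IslandRecord",
    "MasterState",
    "IslandState",
    "relative_improvement",
    "master_handle_solution",
    "adapt_threshold",
    "rank_islands",
    "master_handle_reconfig",
    "slave_receive_phase",
    "slave_send_phase",
    "reconfiguration_check",
    "write_message_log",
    "read_message_log",
]

INITIAL_MASTER_EPSILON = 0.10
DEFAULT_SLAVE_EPSILON = 1e-3
DEFAULT_REFUSAL_WINDOW = 10


@dataclass
class CooperationMessage:
    kind: str  # "solution" | "reconfig_request" | "settings_update"
    sender: int
    payload: object = None  # Solution or ESSSettings or None
    send_time: float = 0.0
    recipient: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("solution", "reconfig_request", "settings_update"):
            raise ValueError(f"unknown message kind {self.kind!r}")
        if self.send_time < 0:
            raise ValueError("send_time must be >= 0")
        if self.kind == "solution" and not np.isfinite(self.payload.cost):
            raise ValueError("solution payloads must carry finite cost")


@dataclass
class IslandRecord:
    """Scoreboard entry: score == n_comm * t_last at all times."""

    n_comm: int = 0
    t_last: float = 0.0
    settings: Optional[ESSSettings] = None

    @property
    def score(self) -> float:
        return self.n_comm * self.t_last


@dataclass
class MasterState:
    """The master's view: incumbent best, spread threshold, scoreboard."""

    best_known: Optional[Solution] = None
    epsilon_master: float = INITIAL_MASTER_EPSILON
    scoreboard: Dict[int, IslandRecord] = field(default_factory=dict)
    refusal_streak: int = 0

    def register_island(self, island_id: int, settings: Optional[ESSSettings] = None) -> None:
        self.scoreboard[island_id] = IslandRecord(settings=settings)


@dataclass
class IslandState:
    """One island's cooperation-side state (its eSS lives elsewhere)."""

    island_id: int
    settings: ESSSettings
    best_known: Optional[Solution] = None
    evals_since_coop: int = 0
    n_sent: int = 0
    n_received: int = 0
    inbox: List[CooperationMessage] = field(default_factory=list)
    outbox: List[CooperationMessage] = field(default_factory=list)


def relative_improvement(old: float, new: float) -> float:
    """(old - new) / |old|; absolute improvement when old == 0."""
    if old == 0.0:
        return old - new
    return (old - new) / abs(old)


# -- master side --------------------------------------------------------------


def master_handle_solution(
    ms: MasterState, msg: CooperationMessage
) -> Tuple[MasterState, Optional[Solution]]:
    """Process an incoming solution; returns the solution to spread, if any.

    Qualified (improvement >= epsilon_master): new incumbent, sender's
    communication count and last-reception time updated, refusal streak
    reset, solution returned for broadcast.  Improving but unqualified:
    incumbent still updated (the threshold always measures against the true
    best) and the refusal streak grows.  Worse: ignored.
    """
    if msg.kind != "solution":
        raise ValueError("master_handle_solution expects a solution message")
    if msg.sender not in ms.scoreboard:
        raise KeyError(f"unknown sender island {msg.sender}")
    sol: Solution = msg.payload
    if ms.best_known is None:
        ms.best_known = sol.copy()
        rec = ms.scoreboard[msg.sender]
        rec.n_comm += 1
        rec.t_last = msg.send_time
        ms.refusal_streak = 0
        return ms, sol
    improvement = relative_improvement(ms.best_known.cost, sol.cost)
    if improvement >= ms.epsilon_master:
        ms.best_known = sol.copy()
        rec = ms.scoreboard[msg.sender]
        rec.n_comm += 1
        rec.t_last = msg.send_time
        ms.refusal_streak = 0
        return ms, sol
    if sol.cost < ms.best_known.cost:
        ms.best_known = sol.copy()
        ms.refusal_streak += 1
        return ms, None
    return ms, None


def adapt_threshold(ms: MasterState, refusal_window: int = DEFAULT_REFUSAL_WINDOW) -> MasterState:
    """Halve the spread threshold after a full window of refusals.

    Over a run the threshold takes the values 0.10, 0.05, 0.025, ...
    """
    if ms.refusal_streak >= refusal_window:
        ms.epsilon_master /= 2.0
        ms.refusal_streak = 0
    return ms


def rank_islands(ms: MasterState) -> List[int]:
    """Island ids descending by score (n_comm * t_last); ties by lower id."""
    return sorted(ms.scoreboard, key=lambda i: (-ms.scoreboard[i].score, i))


def master_handle_reconfig(ms: MasterState, msg: CooperationMessage) -> CooperationMessage:
    """Answer a reconfiguration request with the top-ranked island's settings.

    The requester's own slot is never chosen: if it ranks first, the
    second-ranked island's settings are used.  With an empty scoreboard or
    all-zero scores the update carries no payload (requester keeps its own
    settings).  A single qualified communication is treated as insufficient
    evidence that a configuration works — settings are only spread once
    their island has cooperated at least twice, so one early lucky send
    cannot homogenize the whole archipelago.
    """
    if msg.kind != "reconfig_request":
        raise ValueError("master_handle_reconfig expects a reconfig_request")
    ranking = [i for i in rank_islands(ms) if i != msg.sender]
    payload = None
    if ranking:
        top = ranking[0]
        if ms.scoreboard[top].score > 0 and ms.scoreboard[top].n_comm >= 2:
            payload = ms.scoreboard[top].settings
    return CooperationMessage(
        kind="settings_update",
        sender=-1,  # master
        payload=payload,
        send_time=msg.send_time,
        recipient=msg.sender,
    )


# -- island (slave) side --------------------------------------------------------


def slave_receive_phase(
    island: IslandState, refset: RefSet, problem=None
) -> Tuple[IslandState, RefSet]:
    """Drain the inbox FIFO, funnelling foreign solutions into one slot.

    The first foreign solution ever accepted replaces the worst RefSet
    member, which becomes the cooperative slot; later ones may only replace
    that slot.  A foreign solution no better than the island's best-known
    cost is discarded.  This keeps the island's own population evolving and
    bounds the loss of diversity cooperation could cause.
    """
    pending = list(island.inbox)
    island.inbox.clear()
    for msg in pending:
        if msg.kind != "solution" or msg.payload is None:
            continue  # malformed or non-solution message: skip
        island.n_received += 1
        sol: Solution = msg.payload
        if island.best_known is not None and sol.cost >= island.best_known.cost:
            continue
        island.best_known = sol.copy()
        incoming = sol.copy()
        incoming.is_cooperative = True
        incoming.n_stuck = 0
        incoming.origin = "foreign"
        slot = refset.cooperative_index
        if slot is None:
            refset.sort()
            slot = len(refset) - 1  # worst member
        refset.members[slot] = incoming
        refset.sort()
    return island, refset


def slave_send_phase(
    island: IslandState,
    epsilon_slave: float = DEFAULT_SLAVE_EPSILON,
    current_best: Optional[Solution] = None,
    send_time: float = 0.0,
) -> Optional[CooperationMessage]:
    """Emit the island's best when it beats best-known by at least epsilon.

    The slave epsilon is deliberately small: islands send many good
    solutions and the master decides which qualify for spreading.
    """
    if current_best is None:
        return None
    if island.best_known is not None:
        if relative_improvement(island.best_known.cost, current_best.cost) < epsilon_slave:
            return None
    island.best_known = current_best.copy()
    island.n_sent += 1
    msg = CooperationMessage(
        kind="solution",
        sender=island.island_id,
        payload=current_best.copy(),
        send_time=send_time,
    )
    island.outbox.append(msg)
    return msg


def reconfiguration_check(island: IslandState, n_par: int, send_time: float = 0.0) -> bool:
    """Decide whether the island should request new settings.

    Triggers when the island has burned more than ``n_par * 5000``
    evaluations since its last cooperation, or when it has received more
    solutions than it has sent (others are cooperating much more than
    itself).  On trigger, a request is queued and the counters reset.
    """
    fire = island.evals_since_coop > n_par * 5000 or island.n_received > island.n_sent
    if fire:
        island.outbox.append(
            CooperationMessage(
                kind="reconfig_request", sender=island.island_id, send_time=send_time
            )
        )
        island.evals_since_coop = 0
        island.n_received = 0
        island.n_sent = 0
    return fire


# -- message log ---------------------------------------------------------------


def write_message_log(messages, path) -> None:
    """JSON-lines log: one ``{"t":…, "kind":…, "from":…, "cost":…}`` per message."""
    with open(path, "w") as fh:
        for m in messages:
            cost = m.payload.cost if isinstance(m.payload, Solution) else None
            fh.write(
                json.dumps({"t": m.send_time, "kind": m.kind, "from": m.sender, "cost": cost})
                + "\n"
            )


def read_message_log(path) -> List[CooperationMessage]:
    """Rebuild protocol-relevant messages from a JSON-lines log.

    Solution payloads are reconstructed with empty parameter vectors — the
    master's decisions depend only on cost and time, which is what makes the
    protocol replayable.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            payload = None
            if d["kind"] == "solution":
                payload = Solution(params=np.empty(0), cost=d["cost"], origin="foreign")
            out.append(
                CooperationMessage(
                    kind=d["kind"], sender=d["from"], payload=payload, send_time=d["t"]
                )
            )
    return out
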