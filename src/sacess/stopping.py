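"""Stopping criteria shared by the sequential engine and the island runner.

A search stops on any of: a maximum number of cost evaluations, a maximum
run time, or a value-to-reach (VTR) on the best cost.  The :class:`Stopper`
is checked after every single cost evaluation, so evaluations-to-VTR
measurements are exact to one evaluation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Optional


@dataclass
class StoppingCriteria:
    """At least one of the three criteria must be set."""

    max_evals: Optional[int] = None
    max_time: Optional[float] = None  # seconds
    vtr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_evals is None and self.max_time is None and self.vtr is None:
            raise ValueError("at least one stopping criterion must be set")


class StopSearch(Exception):
    """Raised inside the search loop when a stopping criterion fires."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class Stopper:
    """Evaluates stopping criteria against a problem's evaluation counter.

    ``clock`` is any zero-argument callable returning seconds; the default is
    the wall clock.  Backends with a simulated clock pass their own, which
    keeps every time-dependent decision reproducible.
    """

    def __init__(
        self,
        criteria: StoppingCriteria,
        problem,
        clock: Optional[Callable[[], float]] = None,
    ):
        self.criteria = criteria
        self.problem = problem
        self._clock = clock if clock is not None else time.monotonic
        self._t0 = self._clock()

    def elapsed(self) -> float:
        return self._clock() - self._t0

    def remaining_evals(self) -> float:
        if self.criteria.max_evals is None:
            return float("inf")
        return self.criteria.max_evals - self.problem.n_evals

    def check(self, best_cost: float) -> None:
        """Raise :class:`StopSearch` if any criterion is met."""
        c = self.criteria
        if c.vtr is not None and best_cost <= c.vtr:
            raise StopSearch("vtr")
        if c.max_evals is not None and self.problem.n_evals >= c.max_evals:
            raise StopSearch("max_evals")
        if c.max_time is not None and self.elapsed() >= c.max_time:
            raise StopSearch("max_time")
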