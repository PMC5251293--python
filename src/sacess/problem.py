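"""Estimation problems: dynamics, observations, data and the least-squares cost.

An estimation problem couples a dynamic model (ODE right-hand side plus an
observation map) with experimental time-series data and box bounds on the
unknown parameters.  The cost is the generalized weighted least-squares
mismatch between measured and predicted observables, summed over experiments,
observables and sample times, with an optional quadratic static penalty for
algebraic equality/inequality constraints.

Every cost evaluation increments the problem's evaluation counter, which is
the currency all search budgets are expressed in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import odeint

__all__ = [
    "DynamicModel",
    "Experiment",
    "ExperimentDataset",
    "EstimationProblem",
    "SimulationResult",
    "BoundsError",
    "InvalidModelError",
    "simulate",
    "read_dataset",
    "write_dataset",
    "register_model",
    "load_problem",
    "MODEL_REGISTRY",
]


class BoundsError(ValueError):
    """Parameter vector outside the feasible box."""


class InvalidModelError(ValueError):
    """Model produced non-finite derivatives at its initial state."""


@dataclass
class DynamicModel:
    """A parametric ODE model with an observation map.

    ``rhs(x, p, t)`` returns dx/dt, ``observe(x, p, t)`` maps a state vector
    to the observable vector.  Optional algebraic constraints
    ``eq_constraints(x, y, p)`` / ``ineq_constraints(x, y, p)`` return
    residual vectors (equality residuals should be zero; inequality residuals
    should be non-positive).
    """

    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    initial_state: np.ndarray
    observe: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    n_states: int
    n_observables: int
    eq_constraints: Optional[Callable] = None
    ineq_constraints: Optional[Callable] = None
    rtol: float = 1e-7
    atol: float = 1e-9

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.initial_state.shape != (self.n_states,):
            raise InvalidModelError(
                f"initial_state has shape {self.initial_state.shape}, "
                f"expected ({self.n_states},)"
            )


@dataclass
class Experiment:
    """One experiment: sample times, observed matrix and residual weights.

    ``observed`` is (n_samples, n_observables); NaN marks an unobserved
    entry, which is excluded from the cost.  ``weights`` may be a full
    matrix of the same shape, a length-n_observables vector (per-observable
    diagonal weight) or None (identity).  An experiment may override the
    model's initial state (e.g. different initial conditions per experiment).
    """

    sample_times: np.ndarray
    observed: np.ndarray
    weights: Optional[np.ndarray] = None
    initial_state: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.observed = np.atleast_2d(np.asarray(self.observed, dtype=float))
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.observed.shape[0] != self.sample_times.size:
            raise ValueError("observed rows must match sample_times")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.ndim == 1:
                w = np.broadcast_to(w, self.observed.shape).copy()
            if w.shape != self.observed.shape:
                raise ValueError("weights shape incompatible with observed")
            finite = np.isfinite(self.observed)
            if np.any(w[finite] <= 0):
                raise ValueError("weights must be > 0 where data is observed")
            self.weights = w
        if self.initial_state is not None:
            self.initial_state = np.asarray(self.initial_state, dtype=float)

    @property
    def weight_matrix(self) -> np.ndarray:
        if self.weights is None:
            return np.ones_like(self.observed)
        return self.weights


@dataclass
class ExperimentDataset:
    experiments: list

    def __post_init__(self) -> None:
        self.experiments = list(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def n_residuals(self) -> int:
        """Number of observed (finite) data points across all experiments."""
        return int(sum(np.isfinite(e.observed).sum() for e in self.experiments))


@dataclass
class SimulationResult:
    """Observable trajectories at the sample times, or a failure flag."""

    observables: Optional[np.ndarray]  # (n_times, n_observables)
    states: Optional[np.ndarray]  # (n_times, n_states)
    ok: bool


def simulate(
    model: DynamicModel,
    p: np.ndarray,
    times: Sequence[float],
    initial_state: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Integrate the model at parameters ``p`` and observe at ``times``.

    ``times[0]`` is taken as the initial time.  Uses an adaptive
    stiff-capable integrator (LSODA) with the model's tolerances.  Integrator
    failure is reported through the ``ok`` flag, not an exception, so a
    search can continue past pathological parameter vectors.
    """
    p = np.asarray(p, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be a strictly increasing 1-D vector")
    x0 = model.initial_state if initial_state is None else np.asarray(initial_state, float)

    f0 = np.asarray(model.rhs(x0, p, times[0]), dtype=float)
    if f0.shape != (model.n_states,):
        raise InvalidModelError(f"rhs returned shape {f0.shape}, expected ({model.n_states},)")
    if not np.all(np.isfinite(f0)):
        raise InvalidModelError("rhs is non-finite at the initial state")

    if times.size == 1:
        states = x0[None, :]
    else:
        # LSODA via the low-overhead odeint wrapper; adaptive and
        # stiff-capable, switching between Adams and BDF as needed
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                states, info = odeint(
                    lambda x, t: model.rhs(x, p, t),
                    x0,
                    times,
                    rtol=model.rtol,
                    atol=model.atol,
                    full_output=True,
                )
        except (ValueError, FloatingPointError, OverflowError):
            return SimulationResult(None, None, False)
        if info["message"] != "Integration successful." or not np.all(np.isfinite(states)):
            return SimulationResult(None, None, False)
    obs = np.empty((times.size, model.n_observables))
    for k, t in enumerate(times):
        yk = np.asarray(model.observe(states[k], p, t), dtype=float)
        if yk.shape != (model.n_observables,):
            raise InvalidModelError(
                f"observe returned shape {yk.shape}, expected ({model.n_observables},)"
            )
        obs[k] = yk
    if not np.all(np.isfinite(obs)):
        return SimulationResult(None, None, False)
    return SimulationResult(obs, states, True)


@dataclass
class EstimationProblem:
    """The search space: model + data + box bounds + cost configuration.

    ``log_scale_mask`` selects parameters searched in log10 space (their
    normalized coordinate is linear in log10(p)); bounds of kinetic constants
    routinely span orders of magnitude, where a linear parameterization wastes
    almost the whole box on the top decade.

    The instance owns the global evaluation counter ``n_evals``; every
    :meth:`evaluate_cost` call increments it by exactly one.
    """

    model: DynamicModel
    data: ExperimentDataset
    lower: np.ndarray
    upper: np.ndarray
    log_scale_mask: Optional[np.ndarray] = None
    penalty_weight: float = 1e3
    failure_cost: float = 1e20
    name: str = "problem"
    n_evals: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D vectors of equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("require lower < upper componentwise")
        if self.log_scale_mask is None:
            self.log_scale_mask = np.zeros(self.lower.size, dtype=bool)
        else:
            self.log_scale_mask = np.asarray(self.log_scale_mask, dtype=bool)
        if np.any(self.lower[self.log_scale_mask] <= 0):
            raise ValueError("log-scaled parameters need positive lower bounds")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be nonnegative")

    @property
    def n_par(self) -> int:
        return self.lower.size

    # -- bounds and scaling ------------------------------------------------

    def in_bounds(self, p: np.ndarray) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lower) and np.all(p <= self.upper))

    def clip(self, p: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(p, dtype=float), self.lower, self.upper)

    def normalize(self, p: np.ndarray) -> np.ndarray:
        """Map a parameter vector to the unit cube (log10 on masked dims)."""
        p = np.asarray(p, dtype=float)
        if not self.in_bounds(p):
            raise BoundsError("parameter vector outside bounds")
        lo, hi = self._scaled_bounds()
        q = p.copy()
        q[self.log_scale_mask] = np.log10(q[self.log_scale_mask])
        return (q - lo) / (hi - lo)

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`normalize`; ``u`` must lie in [0, 1]^n_par."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise BoundsError("unit-cube vector outside [0, 1]")
        lo, hi = self._scaled_bounds()
        q = lo + u * (hi - lo)
        q[self.log_scale_mask] = 10.0 ** q[self.log_scale_mask]
        return np.clip(q, self.lower, self.upper)

    def _scaled_bounds(self):
        lo = self.lower.copy()
        hi = self.upper.copy()
        lo[self.log_scale_mask] = np.log10(lo[self.log_scale_mask])
        hi[self.log_scale_mask] = np.log10(hi[self.log_scale_mask])
        return lo, hi

    # -- cost --------------------------------------------------------------

    def cost_only(self, p: np.ndarray) -> float:
        """The cost J at ``p`` without touching the evaluation counter.

        Used by parallel evaluation backends, which account for the whole
        batch in one counter update.
        """
        p = np.asarray(p, dtype=float)
        if not self.in_bounds(p):
            raise BoundsError("parameter vector outside bounds")
        total = 0.0
        for exp in self.data:
            sim = simulate(self.model, p, exp.sample_times, exp.initial_state)
            if not sim.ok:
                return float(self.failure_cost)
            resid = exp.observed - sim.observables
            mask = np.isfinite(exp.observed)
            total += float(np.sum(exp.weight_matrix[mask] * resid[mask] ** 2))
            total += self._penalty(sim, p)
        return total

    def evaluate_cost(self, p: np.ndarray) -> float:
        """Weighted least-squares cost J(p) >= 0; counts one evaluation."""
        cost = self.cost_only(p)
        self.n_evals += 1
        return cost

    def _penalty(self, sim: SimulationResult, p: np.ndarray) -> float:
        if self.model.eq_constraints is None and self.model.ineq_constraints is None:
            return 0.0
        pen = 0.0
        for x, y in zip(sim.states, sim.observables):
            if self.model.eq_constraints is not None:
                h = np.asarray(self.model.eq_constraints(x, y, p), dtype=float)
                pen += float(np.sum(h**2))
            if self.model.ineq_constraints is not None:
                h = np.asarray(self.model.ineq_constraints(x, y, p), dtype=float)
                pen += float(np.sum(np.maximum(h, 0.0) ** 2))
        return self.penalty_weight * pen


# -- CSV data interchange ---------------------------------------------------
#
# Dialect: one row per sample, columns `experiment,time,<obs_1>,...,<obs_k>`
# plus optional `weight_<obs_i>` columns; unobserved entries are blank.


def write_dataset(
    dataset: ExperimentDataset, path, obs_names: Optional[Sequence[str]] = None
) -> None:
    n_obs = dataset.experiments[0].observed.shape[1]
    if obs_names is None:
        obs_names = [f"obs_{i + 1}" for i in range(n_obs)]
    rows = []
    write_weights = any(e.weights is not None for e in dataset)
    for idx, exp in enumerate(dataset):
        for k, t in enumerate(exp.sample_times):
            row = {"experiment": idx + 1, "time": t}
            for j, name in enumerate(obs_names):
                row[name] = exp.observed[k, j]
            if write_weights:
                for j, name in enumerate(obs_names):
                    row[f"weight_{name}"] = exp.weight_matrix[k, j]
            rows.append(row)
    # %.17g guarantees exact float64 round-trips through the text format
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> ExperimentDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    if "experiment" not in df.columns or "time" not in df.columns:
        raise ValueError("dataset CSV needs 'experiment' and 'time' columns")
    obs_names = [
        c for c in df.columns if c not in ("experiment", "time") and not c.startswith("weight_")
    ]
    weight_names = [f"weight_{c}" for c in obs_names]
    have_weights = all(w in df.columns for w in weight_names)
    experiments = []
    for _, sub in df.groupby("experiment", sort=True):
        sub = sub.sort_values("time")
        observed = sub[obs_names].to_numpy(dtype=float)
        weights = sub[weight_names].to_numpy(dtype=float) if have_weights else None
        experiments.append(
            Experiment(sub["time"].to_numpy(dtype=float), observed, weights)
        )
    return ExperimentDataset(experiments)


# -- problem assembly from a YAML descriptor ---------------------------------

MODEL_REGISTRY: dict = {}


def register_model(name: str, factory: Callable) -> None:
    """Register a model factory for YAML problem descriptors.

    The factory receives the descriptor's ``model_args`` mapping and returns
    either a :class:`DynamicModel` or a full synthetic problem object with a
    ``problem`` attribute.
    """
    MODEL_REGISTRY[name] = factory


def load_problem(source) -> EstimationProblem:
    """Build an :class:`EstimationProblem` from a YAML descriptor.

    The descriptor names a registered model and optionally bounds, a CSV
    data file, log-scaling and penalty settings::

        model: kinetic_chain
        model_args: {n_states: 3, n_experiments: 2}
        data: measurements.csv       # optional, overrides generated data
        lower: [0.01, 0.01]          # required for bare DynamicModel factories
        upper: [10.0, 10.0]
        log_scale: true
    """
    if isinstance(source, (str,)) or hasattr(source, "read"):
        with open(source) if isinstance(source, str) else source as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    name = cfg["model"]
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}")
    built = MODEL_REGISTRY[name](**cfg.get("model_args", {}))
    if hasattr(built, "problem"):  # synthetic problem carrying its own data
        problem = built.problem
        if "data" in cfg:
            problem.data = read_dataset(cfg["data"])
        return problem
    model = built
    if "data" not in cfg:
        raise ValueError("descriptor with a bare model needs a 'data' CSV path")
    data = read_dataset(cfg["data"])
    lower = np.asarray(cfg["lower"], dtype=float)
    upper = np.asarray(cfg["upper"], dtype=float)
    log_scale = cfg.get("log_scale", False)
    if isinstance(log_scale, bool):
        mask = np.full(lower.size, log_scale)
    else:
        mask = np.asarray(log_scale, dtype=bool)
    return EstimationProblem(
        model=model,
        data=data,
        lower=lower,
        upper=upper,
        log_scale_mask=mask,
        penalty_weight=cfg.get("penalty_weight", 1e3),
        failure_cost=cfg.get("failure_cost", 1e20),
        name=name,
    )
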