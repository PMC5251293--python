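"""Synthetic estimation problems with known ground truth.

Two families cover the two regimes a global optimizer for kinetic model
calibration faces:

* :func:`make_kinetic_chain` — a Michaelis-Menten reaction chain
  S1 -> S2 -> ... -> Sn observed partially over several experiments with
  different initial substrate loads, mirroring the structure of real
  calibration benchmarks: multi-experiment noisy time series of a subset of
  states, rate constants with bounds spanning three orders of magnitude and
  a log10 search space.
* :func:`make_multimodal` — a closed-form sum-of-wells surface with one
  global minimum at zero and a controlled number of strictly worse local
  minima; microsecond evaluations make convergence statistics over many
  seeds affordable.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .problem import (
    DynamicModel,
    EstimationProblem,
    Experiment,
    ExperimentDataset,
    register_model,
    simulate,
)

__all__ = [
    "SyntheticProblem",
    "make_kinetic_chain",
    "make_multimodal",
    "generate_data",
]

# deterministic tabulated true rates for the chain (cycled as needed)
_VMAX_TABLE = (1.2, 0.8, 1.5, 0.9, 1.1)
_KM_TABLE = (0.4, 0.7, 0.3, 0.6, 0.5)

# asymmetric log-uniform box spanning three decades, p_true/100 .. p_true*10,
# so the log-midpoint of the box sits half a decade below the truth and a
# center start cannot win trivially
_BOUND_BELOW = 100.0
_BOUND_ABOVE = 10.0


@dataclass
class SyntheticProblem:
    """An estimation problem bundled with its generating truth."""

    problem: EstimationProblem
    p_true: np.ndarray
    vtr_suggested: float
    label: str
    extras: dict = field(default_factory=dict)


class _ChainRHS:
    """Michaelis-Menten chain derivatives; picklable for process backends."""

    def __init__(self, n_states: int):
        self.n_states = n_states

    def __call__(self, x, p, t):
        vmax = p[0::2]
        km = p[1::2]
        rates = vmax * x[:-1] / (km + np.abs(x[:-1]))
        dx = np.empty(self.n_states)
        dx[0] = -rates[0]
        dx[1:-1] = rates[:-1] - rates[1:]
        dx[-1] = rates[-1]
        return dx


class _ChainObserve:
    """Observe every state but the first (a strict subset)."""

    def __init__(self, n_states: int):
        self.n_states = n_states

    def __call__(self, x, p, t):
        return x[1:]


def make_kinetic_chain(
    n_states: int = 3,
    n_experiments: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 21,
    t_end: float = 10.0,
) -> SyntheticProblem:
    """A mass-action chain with Michaelis-Menten steps and partial observation.

    Each of the ``n_states - 1`` conversion steps contributes two parameters
    (Vmax, Km), so ``n_states=3`` gives 4 rate parameters and 2 observables.
    Experiments differ in the initial substrate load.  Bounds span three
    decades, [p_true/100, p_true*10], with the log10 mask on; observation noise is
    additive Gaussian with per-observable standard deviation
    ``noise_sd * max|y|``, and residual weights are 1/max(ym)^2 per
    observable.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    n_steps = n_states - 1
    p_true = np.empty(2 * n_steps)
    p_true[0::2] = [_VMAX_TABLE[k % len(_VMAX_TABLE)] for k in range(n_steps)]
    p_true[1::2] = [_KM_TABLE[k % len(_KM_TABLE)] for k in range(n_steps)]

    model = DynamicModel(
        rhs=_ChainRHS(n_states),
        initial_state=np.r_[1.0, np.zeros(n_states - 1)],
        observe=_ChainObserve(n_states),
        n_states=n_states,
        n_observables=n_states - 1,
    )
    times = np.linspace(0.0, t_end, n_samples)
    initial_states = [
        np.r_[1.0 + 0.5 * e, np.zeros(n_states - 1)] for e in range(n_experiments)
    ]
    data = generate_data(
        model,
        p_true,
        times,
        noise_sd,
        seed,
        initial_states=initial_states,
        weight_scheme="inverse_max_square",
    )
    problem = EstimationProblem(
        model=model,
        data=data,
        lower=p_true / _BOUND_BELOW,
        upper=p_true * _BOUND_ABOVE,
        log_scale_mask=np.ones(p_true.size, dtype=bool),
        name=f"kinetic_chain_{n_states}",
    )
    vtr = max(1e-6, 1.2 * data.n_residuals * noise_sd**2)
    return SyntheticProblem(
        problem=problem,
        p_true=p_true,
        vtr_suggested=vtr,
        label=f"kinetic_chain(n_states={n_states}, n_experiments={n_experiments})",
        extras={"times": times, "initial_states": initial_states},
    )


class _WellSurface:
    """min_k ||p - c_k||^2 + h_k: piecewise-quadratic multimodal landscape."""

    def __init__(self, centers: np.ndarray, offsets: np.ndarray):
        self.centers = centers
        self.offsets = offsets

    def __call__(self, p) -> float:
        d2 = np.sum((self.centers - np.asarray(p, float)) ** 2, axis=1)
        return float(np.min(d2 + self.offsets))


class _WellObserve:
    def __init__(self, surface: _WellSurface):
        self.surface = surface

    def __call__(self, x, p, t):
        return np.array([np.sqrt(self.surface(p))])


def _zero_rhs(x, p, t):
    return np.zeros(1)


def make_multimodal(n_par: int = 10, n_minima: int = 8, seed: int = 0) -> SyntheticProblem:
    """A sum-of-wells surface with a unique global minimum of value 0.

    Wells are quadratic bowls ``||p - c_k||^2 + h_k`` combined by a
    pointwise minimum; ``h_0 = 0`` at the seed-derived global center and
    ``h_k >= 1`` elsewhere, with centers kept at least distance 2 apart so
    every center is a genuine local minimum of the surface.  Local-well
    floors deepen toward the global center (``h_k`` grows with the distance
    of ``c_k`` from ``c_0``), giving the big-valley structure that rugged
    kinetic estimation landscapes exhibit: good local optima carry
    information about where the global optimum lies.  ``n_minima=1``
    degenerates to a single convex well.  Wrapped as a zero-dynamics
    estimation problem (one sample at t=0, datum 0) whose cost equals the
    surface exactly.
    """
    if n_minima < 1:
        raise ValueError("n_minima must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.empty((n_minima, n_par))
    centers[0] = rng.uniform(-4.0, 4.0, size=n_par)
    k = 1
    while k < n_minima:
        cand = rng.uniform(-4.0, 4.0, size=n_par)
        if np.min(np.linalg.norm(centers[:k] - cand, axis=1)) >= 2.0:
            centers[k] = cand
            k += 1
    # h_k - h_j <= 0.15*||c_k - c_j|| < ||c_k - c_j||^2 at separation >= 2,
    # so every center stays a strict local minimum
    dist_to_global = np.linalg.norm(centers[1:] - centers[0], axis=1)
    offsets = np.r_[0.0, 1.0 + 0.15 * dist_to_global]
    surface = _WellSurface(centers, offsets)

    model = DynamicModel(
        rhs=_zero_rhs,
        initial_state=np.zeros(1),
        observe=_WellObserve(surface),
        n_states=1,
        n_observables=1,
    )
    data = ExperimentDataset([Experiment(np.array([0.0]), np.zeros((1, 1)))])
    problem = EstimationProblem(
        model=model,
        data=data,
        lower=np.full(n_par, -5.0),
        upper=np.full(n_par, 5.0),
        name=f"multimodal_{n_par}d_{n_minima}",
    )
    return SyntheticProblem(
        problem=problem,
        p_true=centers[0].copy(),
        vtr_suggested=1e-3,
        label=f"multimodal(n_par={n_par}, n_minima={n_minima})",
        extras={"surface": surface, "centers": centers, "offsets": offsets},
    )


def generate_data(
    model: DynamicModel,
    p_true: np.ndarray,
    times: Sequence[float],
    noise_sd: float,
    seed: int,
    initial_states: Optional[Sequence[np.ndarray]] = None,
    weight_scheme: Optional[str] = None,
) -> ExperimentDataset:
    """Simulate at the true parameters and add scaled Gaussian noise.

    Noise per observable has standard deviation ``noise_sd * scale`` where
    ``scale`` is that observable's maximum absolute signal in the
    experiment.  ``weight_scheme='inverse_max_square'`` attaches the
    per-observable weights 1/max(ym)^2 commonly used to balance residuals
    across observables of different magnitudes.
    """
    rng = np.random.default_rng(seed)
    if initial_states is None:
        initial_states = [None]
    experiments = []
    times = np.asarray(times, dtype=float)
    for x0 in initial_states:
        sim = simulate(model, p_true, times, initial_state=x0)
        if not sim.ok:
            raise RuntimeError("simulation at the true parameters failed")
        y = sim.observables
        scale = np.max(np.abs(y), axis=0)
        ym = y + rng.normal(size=y.shape) * (noise_sd * scale)
        weights = None
        if weight_scheme == "inverse_max_square":
            denom = np.maximum(np.max(np.abs(ym), axis=0), 1e-12)
            weights = 1.0 / denom**2
        elif weight_scheme is not None:
            raise ValueError(f"unknown weight scheme {weight_scheme!r}")
        experiments.append(Experiment(times, ym, weights, initial_state=x0))
    return ExperimentDataset(experiments)


register_model("kinetic_chain", make_kinetic_chain)
register_model("multimodal", make_multimodal)
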