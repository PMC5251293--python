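import numpy as np
import pytest

from sacess.problem import (
    DynamicModel,
    EstimationProblem,
    Experiment,
    ExperimentDataset,
)


def make_algebraic_problem(fn, lower, upper, log_scale_mask=None):
    """Wrap a nonnegative closed-form surface f(p) as an estimation problem.

    Zero dynamics, a single sample at t=0 with datum 0 and prediction
    sqrt(f(p)), so evaluate_cost(p) == f(p) exactly.  Used to exercise the
    search machinery with microsecond cost evaluations.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)

    model = DynamicModel(
        rhs=lambda x, p, t: np.zeros(1),
        initial_state=np.zeros(1),
        observe=lambda x, p, t: np.array([np.sqrt(fn(p))]),
        n_states=1,
        n_observables=1,
    )
    data = ExperimentDataset([Experiment(np.array([0.0]), np.zeros((1, 1)))])
    return EstimationProblem(
        model=model, data=data, lower=lower, upper=upper, log_scale_mask=log_scale_mask
    )


@pytest.fixture
def sphere5():
    """5-D convex quadratic centered off-origin, bounds [-5, 5]."""
    c = np.array([1.3, -0.7, 2.1, 0.4, -1.9])
    return make_algebraic_problem(
        lambda p: float(np.sum((np.asarray(p) - c) ** 2)), [-5.0] * 5, [5.0] * 5
    )


@pytest.fixture
def decay_model():
    """Linear decay dx/dt = -p1 * x, x0 = 1, fully observed."""
    return DynamicModel(
        rhs=lambda x, p, t: -p[0] * x,
        initial_state=np.array([1.0]),
        observe=lambda x, p, t: x,
        n_states=1,
        n_observables=1,
    )


@pytest.fixture(scope="session")
def chain3():
    from sacess.bench import make_kinetic_chain

    return make_kinetic_chain(3, 2, noise_sd=0.0, seed=0)
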