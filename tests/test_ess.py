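import numpy as np
import pytest

from sacess.ess import (
    ESSSettings,
    EssRun,
    RefSet,
    Solution,
    apply_stagnation,
    build_refset,
    check_duplicates,
    combination_box,
    combine_pair,
    generate_diverse_set,
    go_beyond,
    run_ess,
    update_refset,
)
from sacess.stopping import StoppingCriteria

from conftest import make_algebraic_problem


def unit_problem(n=2, fn=None):
    fn = fn if fn is not None else (lambda p: float(np.sum(np.asarray(p) ** 2)))
    return make_algebraic_problem(fn, [0.0] * n, [1.0] * n)


def sol(params, cost, **kw):
    return Solution(np.asarray(params, float), cost, **kw)


class TestDiverseSet:
    def test_latin_hypercube_bin_property(self):
        prob = unit_problem(3)
        out = generate_diverse_set(prob, 100, rng=5)
        u = np.array([prob.normalize(s.params) for s in out])
        for d in range(3):
            bins = np.floor(u[:, d] * 100).astype(int)
            assert sorted(bins) == list(range(100))

    def test_single_solution_in_bounds_and_evaluated(self):
        prob = unit_problem(2)
        (s,) = generate_diverse_set(prob, 1, rng=0)
        assert prob.in_bounds(s.params) and np.isfinite(s.cost)

    def test_seed_determinism(self):
        prob = unit_problem(4)
        a = generate_diverse_set(prob, 20, rng=7)
        b = generate_diverse_set(prob, 20, rng=7)
        assert all(np.array_equal(x.params, y.params) for x, y in zip(a, b))

    def test_uniform_mode(self):
        prob = unit_problem(2)
        out = generate_diverse_set(prob, 10, rng=1, method="uniform")
        assert len(out) == 10


class TestBuildRefset:
    def test_exact_size_keeps_all_sorted(self):
        diverse = [sol([0.1, 0.1], c) for c in [5.0, 1.0, 3.0, 2.0]]
        rs = build_refset(diverse, ESSSettings(dim_refset=4), rng=0)
        assert [m.cost for m in rs.members] == [1.0, 2.0, 3.0, 5.0]

    def test_best_half_always_present(self):
        diverse = [sol([0.1, 0.1], float(c)) for c in range(1, 11)]
        for seed in range(30):
            rs = build_refset(diverse, ESSSettings(dim_refset=4), rng=seed)
            costs = {m.cost for m in rs.members}
            assert {1.0, 2.0} <= costs
            assert len(rs) == 4

    def test_degenerate_equal_costs(self):
        diverse = [sol([0.1 * k, 0.0], 7.0) for k in range(8)]
        rs = build_refset(diverse, ESSSettings(dim_refset=4), rng=3)
        assert len(rs) == 4
        assert [m.cost for m in rs.members] == sorted(m.cost for m in rs.members)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_refset([sol([0.0, 0.0], 1.0)], ESSSettings(dim_refset=4))


def brute_force_min_pair_distance(refset, problem):
    u = [problem.normalize(m.params) for m in refset.members]
    best = np.inf
    for i in range(len(u)):
        for j in range(i + 1, len(u)):
            best = min(best, float(np.max(np.abs(u[i] - u[j]))))
    return best


class TestCheckDuplicates:
    def test_close_pair_replaces_worse_member(self):
        prob = unit_problem(2)
        rs = RefSet(
            [
                sol([0.500, 0.500], 1.0),
                sol([0.5004, 0.5002], 2.0),  # max diff 4e-4 < 1e-3
                sol([0.9, 0.9], 3.0),
                sol([0.1, 0.9], 4.0),
            ]
        )
        check_duplicates(rs, prob, ESSSettings(dim_refset=4), rng=0)
        costs = [m.cost for m in rs.members]
        assert 1.0 in costs and 2.0 not in costs
        assert brute_force_min_pair_distance(rs, prob) >= 1e-3

    def test_distant_members_untouched(self):
        prob = unit_problem(2)
        members = [sol([0.1 * k, 0.9 - 0.2 * k], float(k)) for k in range(4)]
        rs = RefSet([m.copy() for m in members])
        check_duplicates(rs, prob, ESSSettings(dim_refset=4), rng=0)
        assert [m.cost for m in rs.members] == [m.cost for m in members]

    def test_cluster_resolved_to_fixed_point(self):
        prob = unit_problem(2)
        rs = RefSet(
            [
                sol([0.5, 0.5], 1.0),
                sol([0.5001, 0.5001], 2.0),
                sol([0.5002, 0.4999], 3.0),
                sol([0.9, 0.1], 4.0),
            ]
        )
        check_duplicates(rs, prob, ESSSettings(dim_refset=4), rng=1)
        assert brute_force_min_pair_distance(rs, prob) >= 1e-3
        assert len(rs) == 4


class TestCombinePair:
    def test_identical_parents_degenerate_box(self):
        prob = unit_problem(3)
        p = sol([0.3, 0.6, 0.2], 1.0)
        off = combine_pair(prob, p, p, 0, 1, 10, rng=0)
        np.testing.assert_allclose(off, p.params, atol=1e-12)

    def test_offspring_inside_box_and_uniform(self):
        from scipy.stats import kstest

        prob = unit_problem(2)
        pi, pj = sol([0.4, 0.2], 1.0), sol([0.8, 0.9], 2.0)
        rank_i, rank_j, dim = 0, 3, 10
        beta = (rank_j - rank_i) / (dim - 1)
        lo, hi = combination_box(pi.params, pj.params, beta)
        rng = np.random.default_rng(11)
        offs = np.array([combine_pair(prob, pi, pj, rank_i, rank_j, dim, rng) for _ in range(10_000)])
        box_lo, box_hi = np.minimum(lo, hi), np.maximum(lo, hi)
        clip_lo = np.maximum(box_lo, 0.0)
        clip_hi = np.minimum(box_hi, 1.0)
        assert np.all(offs >= clip_lo - 1e-12) and np.all(offs <= clip_hi + 1e-12)
        for d in range(2):
            if box_lo[d] >= 0 and box_hi[d] <= 1:  # unclipped: exactly uniform
                stat = kstest(offs[:, d], "uniform", args=(box_lo[d], box_hi[d] - box_lo[d]))
                assert stat.pvalue > 0.01

    def test_one_dimensional_formula(self):
        prob = make_algebraic_problem(lambda p: float(p[0] ** 2), [-2.0], [2.0])
        pi, pj = sol([0.0], 1.0), sol([1.0], 2.0)
        rng = np.random.default_rng(4)
        offs = np.array([combine_pair(prob, pi, pj, 0, 0, 10, rng)[0] for _ in range(2000)])
        # beta = 0: box is [-0.5, 0.5], well inside bounds
        assert offs.min() >= -0.5 - 1e-9 and offs.max() <= 0.5 + 1e-9
        assert offs.min() < -0.4 and offs.max() > 0.4


class TestGoBeyond:
    def test_worse_child_returned_without_evaluations(self):
        prob = unit_problem(2)
        parent = sol([0.2, 0.2], 1.0)
        child = sol([0.4, 0.4], 2.0)
        before = prob.n_evals
        out = go_beyond(parent, child, prob, rng=0)
        assert out is child and prob.n_evals == before

    def test_linear_cost_marches_to_bound(self):
        # strictly decreasing cost toward p=0: every step improves until
        # clipping halts progress
        prob = make_algebraic_problem(lambda p: float(p[0]), [0.0], [1.0])
        parent = sol([0.9], 0.9)
        child = sol([0.7], 0.7)
        trace = []
        orig = prob.evaluate_cost

        def record(p):
            c = orig(p)
            trace.append(c)
            return c

        out = go_beyond(parent, child, prob, rng=3, evaluate=record)
        assert out.cost < child.cost
        improving = trace[:-1]  # the last sample is the first non-improvement
        assert all(b < a for a, b in zip(improving, improving[1:]))

    def test_quadratic_valley_not_worse_than_child(self):
        prob = make_algebraic_problem(lambda p: float((p[0] - 0.5) ** 2), [0.0], [1.0])
        parent = sol([0.1], 0.16)
        child = sol([0.25], 0.0625)
        out = go_beyond(parent, child, prob, rng=2)
        assert out.cost <= child.cost


class TestUpdateRefset:
    def _refset(self):
        return RefSet([sol([0.1, 0.1], 4.0), sol([0.2, 0.2], 6.0), sol([0.3, 0.3], 8.0), sol([0.4, 0.4], 9.0)])

    def test_offspring_replaces_only_its_parent(self):
        rs = self._refset()
        update_refset(rs, {1: [sol([0.5, 0.5], 5.0)]})
        assert [m.cost for m in rs.members] == [4.0, 5.0, 8.0, 9.0]
        assert rs.members[1].n_stuck == 0
        assert all(m.n_stuck == 1 for m in rs.members if m.cost != 5.0)

    def test_better_than_global_but_worse_than_parent_is_dropped(self):
        rs = self._refset()
        # offspring of the cost-8 slot, better than the global best 4 ... no:
        # better than others but worse than its own parent
        update_refset(rs, {1: [sol([0.5, 0.5], 7.0)]})
        costs = [m.cost for m in rs.members]
        assert 7.0 not in costs and costs == [4.0, 6.0, 8.0, 9.0]

    def test_only_best_offspring_of_a_slot_enters(self):
        rs = RefSet([sol([0.1, 0.1], 4.0), sol([0.2, 0.2], 10.0), sol([0.3, 0.3], 11.0), sol([0.4, 0.4], 12.0)])
        update_refset(rs, {0: [sol([0.5, 0.5], 5.0), sol([0.6, 0.6], 3.0)]})
        assert rs.members[0].cost == 3.0
        assert 5.0 not in [m.cost for m in rs.members]

    def test_cooperative_flag_persists_through_own_offspring(self):
        rs = self._refset()
        rs.members[2].is_cooperative = True
        update_refset(rs, {2: [sol([0.9, 0.9], 1.0)]})
        flagged = [m for m in rs.members if m.is_cooperative]
        assert len(flagged) == 1 and flagged[0].cost == 1.0

    def test_unknown_slot_rejected(self):
        with pytest.raises(ValueError):
            update_refset(self._refset(), {9: [sol([0.5, 0.5], 1.0)]})


class TestStagnation:
    def test_member_at_limit_replaced(self):
        prob = unit_problem(2)
        rs = RefSet([sol([0.1, 0.1], 1.0), sol([0.2, 0.2], 2.0), sol([0.3, 0.3], 3.0), sol([0.4, 0.4], 4.0)])
        rs.members[3].n_stuck = 20
        apply_stagnation(rs, prob, ESSSettings(stagnation_limit=20), rng=0)
        assert 4.0 not in [m.cost for m in rs.members]
        assert all(m.n_stuck < 20 for m in rs.members)

    def test_cooperative_member_has_longer_leash(self):
        prob = unit_problem(2)
        rs = RefSet([sol([0.1, 0.1], 1.0), sol([0.2, 0.2], 2.0), sol([0.3, 0.3], 3.0), sol([0.4, 0.4], 4.0)])
        rs.members[2].n_stuck = 20
        rs.members[2].is_cooperative = True
        target_cost = rs.members[2].cost
        apply_stagnation(
            rs, prob, ESSSettings(stagnation_limit=20, cooperative_stagnation_factor=2.0), rng=0
        )
        assert target_cost in [m.cost for m in rs.members]  # kept: 20 < 40

    def test_below_limit_is_identity(self):
        prob = unit_problem(2)
        rs = RefSet([sol([0.1, 0.1], 1.0), sol([0.2, 0.2], 2.0), sol([0.3, 0.3], 3.0), sol([0.4, 0.4], 4.0)])
        before = [id(m) for m in rs.members]
        apply_stagnation(rs, prob, ESSSettings(), rng=0)
        assert [id(m) for m in rs.members] == before


class TestRunEss:
    def test_vtr_above_initial_best_stops_immediately(self, sphere5):
        res = run_ess(sphere5, ESSSettings(), StoppingCriteria(max_evals=10_000, vtr=1e6), rng=0)
        sphere5.n_evals = 0
        assert res.stop_reason == "vtr" and res.n_iterations == 0

    def test_determinism_identical_traces(self):
        for _ in range(2):
            results = []
            for _ in range(2):
                prob = unit_problem(3)
                res = run_ess(prob, ESSSettings(), StoppingCriteria(max_evals=2000), rng=42)
                results.append(res)
            a, b = results
            assert a.trace == b.trace
            np.testing.assert_array_equal(a.best.params, b.best.params)

    def test_missing_stopping_criteria_is_config_error(self, sphere5):
        with pytest.raises(ValueError):
            StoppingCriteria()

    def test_best_cost_non_increasing_along_trace(self):
        prob = unit_problem(4)
        res = run_ess(prob, ESSSettings(), StoppingCriteria(max_evals=3000), rng=9)
        costs = [r["best_cost"] for r in res.trace]
        assert all(b <= a for a, b in zip(costs, costs[1:]))

    def test_emitted_parameters_always_in_bounds(self):
        seen = []
        fn = lambda p: float(np.sum((np.asarray(p) - 0.3) ** 2))

        def spy(p):
            seen.append(np.array(p))
            return fn(p)

        prob = unit_problem(3, fn=spy)
        run_ess(prob, ESSSettings(), StoppingCriteria(max_evals=2000), rng=5)
        arr = np.array(seen)
        assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_random_search_ablation_is_much_worse(self, sphere5):
        """With combination and go-beyond off and local search disabled, the
        engine degenerates to stagnation-driven random restarts; full eSS
        should beat that baseline by a wide margin on a convex quadratic."""
        from sacess.stopping import Stopper, StopSearch

        def run_variant(seed, ablate):
            prob = make_algebraic_problem(
                lambda p: float(np.sum((np.asarray(p) - 0.5) ** 2)), [-5.0] * 5, [5.0] * 5
            )
            settings = ESSSettings(
                local_n1=None if ablate else 500, stagnation_limit=1 if ablate else 20
            )
            stopper = Stopper(StoppingCriteria(max_evals=5000), prob)
            run = EssRun(
                prob,
                settings,
                np.random.default_rng(seed),
                stopper,
                combine_enabled=not ablate,
                go_beyond_enabled=not ablate,
            )
            try:
                run.initialize()
                while True:
                    run.step()
            except StopSearch:
                pass
            return run.best.cost

        full = [run_variant(s, False) for s in range(20)]
        random_only = [run_variant(s, True) for s in range(20)]
        assert np.median(random_only) >= 10 * np.median(full)


class TestRefsetInvariantFuzz:
    def test_operations_preserve_size_and_order(self):
        """Random sequences of public RefSet operations keep it sorted, at
        fixed size, with at most one cooperative member."""
        prob = unit_problem(3)
        rng = np.random.default_rng(123)
        settings = ESSSettings(dim_refset=6)
        diverse = generate_diverse_set(prob, 12, rng=rng)
        rs = build_refset(diverse, settings, rng=rng)
        for _ in range(300):
            op = rng.integers(4)
            if op == 0:
                check_duplicates(rs, prob, settings, rng)
            elif op == 1:
                k = int(rng.integers(len(rs)))
                offspring = [
                    Solution(prob.denormalize(rng.uniform(size=3)), float(rng.uniform(0, 3)))
                    for _ in range(int(rng.integers(1, 4)))
                ]
                update_refset(rs, {k: offspring})
            elif op == 2:
                rs.members[int(rng.integers(len(rs)))].n_stuck += int(rng.integers(25))
                apply_stagnation(rs, prob, settings, rng)
            else:
                rs.members[int(rng.integers(len(rs)))].is_cooperative = True
                for m in rs.members[1:]:
                    if sum(x.is_cooperative for x in rs.members) > 1:
                        m.is_cooperative = False
                rs.sort()
            rs.validate()
            assert len(rs) == 6
            assert all(prob.in_bounds(m.params) for m in rs.members)
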