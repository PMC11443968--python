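"""Constant-acceleration planning: cost, constrained optimum, fallback, noise."""

import numpy as np
import pytest

from ceimerge import (Belief, InfeasiblePlanError, PlannerConfig, SimParams,
                      VehicleState, fallback_plan,
                      optimize_plan, perturb_plan, plan_cost, resistance)
from ceimerge.planner import rollout, rollout_batch
from ceimerge.risk import plan_positions_risk


def _config(**kw):
    base = dict(v_desired=10.0, a_max=2.0, noise_sd=0.0,
                include_resistance_in_rollout=False)
    base.update(kw)
    return PlannerConfig(**base)


def brute_force_optimum(state, config, params, risk_fn, risk_cap):
    """Independent oracle: exhaustive 1e-3-step scan over the input range."""
    best = (None, np.inf)
    accels = np.arange(-config.a_max, config.a_max + 1e-9, 1e-3)
    n = params.n_plan_steps
    vs, ss = rollout_batch(state.v, state.s, accels, n, params.dt,
                           config.include_resistance_in_rollout)
    dev = vs - config.v_desired
    costs = (dev * dev).sum(axis=1) + n * accels ** 2
    if risk_fn is not None and risk_cap < 1.0:
        stride = params.belief_stride
        idx = stride * np.arange(1, params.n_belief_points + 1) - 1
        risks = np.asarray(risk_fn(ss[:, idx]))
        ok = risks <= risk_cap + 1e-12
    else:
        ok = np.ones(accels.size, bool)
    if not ok.any():
        return None, np.inf
    j = np.flatnonzero(ok)[np.argmin(costs[ok])]
    return float(accels[j]), float(costs[j])


def _belief_at(mus, sigmas, params):
    offsets = np.arange(1, params.n_belief_points + 1) / params.fb
    return Belief(t0=0.0, offsets=offsets, mus=np.asarray(mus, float),
                  sigmas=np.asarray(sigmas, float), phi=params.phi)


class TestPlanCost:
    def test_stationary_optimum_is_free(self, params):
        state = VehicleState(s=0.0, v=10.0)
        assert plan_cost(0.0, state, _config(), params) == 0.0

    def test_closed_form_value(self, params):
        # v = v_d, resistance off, a = 1: J = 0.0025 * sum k^2 + 120
        state = VehicleState(s=0.0, v=10.0)
        k = np.arange(1, 121)
        expected = 0.0025 * (k ** 2).sum() + 120
        assert plan_cost(1.0, state, _config(), params) == pytest.approx(
            expected)
        assert expected == pytest.approx(1578.05)

    def test_nonzero_input_never_beats_stationary(self, params):
        state = VehicleState(s=0.0, v=10.0)
        for a in (-1.5, -0.3, 0.4, 2.0):
            assert plan_cost(a, state, _config(), params) > 0.0


class TestOptimizePlan:
    def test_unconstrained_optimum_without_resistance(self, params):
        state = VehicleState(s=0.0, v=10.0)
        plan = optimize_plan(state, None, 1.0, _config(), params)
        assert plan.a_planned == pytest.approx(0.0, abs=1e-9)

    def test_resistance_needs_positive_compensation(self, params):
        state = VehicleState(s=0.0, v=10.0)
        cfg = _config(include_resistance_in_rollout=True)
        plan = optimize_plan(state, None, 1.0, cfg, params)
        assert 0.0 < plan.a_planned < resistance(10.0)

    def test_matches_brute_force_on_random_instances(self, params, geometry,
                                                     rng):
        mismatches = 0
        for _ in range(25):
            v0 = rng.uniform(5, 14)
            s0 = rng.uniform(60, 95)
            cfg = _config(v_desired=v0,
                          include_resistance_in_rollout=bool(rng.integers(2)))
            mus = s0 + rng.uniform(0.5, 1.5) * v0 * np.arange(1, 25) / 4.0
            sigmas = 0.5 * (np.arange(1, 25) / 4.0) ** 2 * rng.uniform(0.3, 0.6)
            belief = _belief_at(mus, sigmas, params)

            def risk_fn(pos):
                return plan_positions_risk(pos, belief, geometry)

            cap = rng.uniform(0.05, 0.6)
            state = VehicleState(s=s0, v=v0)
            a_ref, c_ref = brute_force_optimum(state, cfg, params, risk_fn, cap)
            try:
                plan = optimize_plan(state, belief, cap, cfg, params, risk_fn)
            except InfeasiblePlanError:
                assert a_ref is None
                continue
            assert a_ref is not None
            assert abs(plan.a_planned - a_ref) <= 1e-3 + 1e-12
            c_got = plan_cost(plan.a_planned, state, cfg, params)
            assert c_got <= c_ref * (1 + 1e-6) + 1e-9

    def test_feasible_plan_respects_cap(self, params, geometry):
        # the other vehicle is projected ~8 m ahead of the ego path: keeping
        # speed is risky, braking opens the gap and is feasible
        state = VehicleState(s=90.0, v=10.0)
        mus = 98.0 + 10.5 * np.arange(1, 25) / 4.0
        belief = _belief_at(mus, np.full(24, 2.0), params)

        def risk_fn(pos):
            return plan_positions_risk(pos, belief, geometry)

        cap = 0.3
        plan = optimize_plan(state, belief, cap, _config(), params, risk_fn)
        stride = SimParams().belief_stride
        idx = stride * np.arange(1, 25) - 1
        assert float(risk_fn(plan.waypoints[idx])) <= cap + 1e-9

    def test_adversarial_belief_forces_deviation(self, params, geometry):
        # belief concentrated exactly on the ego constant-speed path
        state = VehicleState(s=94.0, v=10.0)
        offsets = np.arange(1, 25) / 4.0
        mus = 94.0 + 10.0 * offsets
        belief = _belief_at(mus, np.full(24, 0.3), params)

        def risk_fn(pos):
            return plan_positions_risk(pos, belief, geometry)

        try:
            plan = optimize_plan(state, belief, 0.01, _config(), params,
                                 risk_fn)
        except InfeasiblePlanError:
            return  # acceptable: no feasible input at all
        assert abs(plan.a_planned) > 0.1  # pushed away from the free optimum


class TestFallback:
    def test_behind_brakes_ahead_accelerates(self, params):
        cfg = _config()
        behind = fallback_plan(VehicleState(s=60.0, v=10.0), 70.0, cfg, params)
        ahead = fallback_plan(VehicleState(s=70.0, v=10.0), 60.0, cfg, params)
        tie = fallback_plan(VehicleState(s=65.0, v=10.0), 65.0, cfg, params)
        assert behind.a_planned == -2.0
        assert ahead.a_planned == 2.0
        assert tie.a_planned == -2.0  # conservative tie-break


class TestPerturbPlan:
    def test_zero_noise_is_identity(self, params):
        plan = optimize_plan(VehicleState(s=0.0, v=10.0), None, 1.0,
                             _config(), params)
        assert perturb_plan(plan, 0.0) is plan

    def test_monte_carlo_sd(self, params, rng):
        plan = optimize_plan(VehicleState(s=0.0, v=10.0), None, 1.0,
                             _config(), params)
        eps = [perturb_plan(plan, 0.14, rng).a_executed - plan.a_planned
               for _ in range(100_000)]
        assert np.std(eps) == pytest.approx(0.14, rel=0.01)

    def test_waypoints_untouched_by_noise(self, params, rng):
        plan = optimize_plan(VehicleState(s=0.0, v=10.0), None, 1.0,
                             _config(), params)
        noisy = perturb_plan(plan, 0.5, rng)
        assert noisy.a_planned == plan.a_planned
        assert np.array_equal(noisy.waypoints, plan.waypoints)


class TestRollout:
    def test_batch_matches_scalar(self, rng):
        accels = np.array([-1.5, 0.0, 0.7, 2.0])
        vb, sb = rollout_batch(9.0, 50.0, accels, 60, 0.05, True)
        for i, a in enumerate(accels):
            vs, ss = rollout(9.0, 50.0, a, 60, 0.05, True)
            assert np.allclose(vb[i], vs, atol=1e-12)
            assert np.allclose(sb[i], ss, atol=1e-12)

    def test_invariants(self):
        vs, ss = rollout(1.0, 0.0, -2.0, 120, 0.05, True)
        assert (vs >= 0).all()
        assert (np.diff(ss) >= 0).all()
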