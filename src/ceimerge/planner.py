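"""Constant-acceleration planning under a risk cap.

A driver's plan is a single constant acceleration input held over the
planning horizon, chosen to minimise a comfort/speed cost

    J(a) = sum_k (v_k - v_d)^2 + sum_k a^2

subject to the perceived collision risk of the resulting trajectory staying
below a cap. Safety is a *constraint*, not a cost term: the driver satisfices
rather than trades off collision risk against comfort. The one-dimensional
problem is solved deterministically on a 1 mm/s^2 lattice: a coarse grid scan
locates the feasible basin(s), and a fine lattice scan around the best cell
and around every feasibility boundary refines the answer, so the result is
reproducible and identical to a brute-force lattice search. When no feasible
acceleration exists the caller falls back to full braking (if behind) or full
acceleration (if ahead).

The executed input is the planned one plus a motor-noise offset drawn once
per replan and frozen until the next replan; risk is always evaluated on the
*planned* (noise-free) trajectory, which is what the driver believes they are
doing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .scenario import SimParams, VehicleState

__all__ = [
    "Plan",
    "PlannerConfig",
    "InfeasiblePlanError",
    "plan_cost",
    "optimize_plan",
    "fallback_plan",
    "perturb_plan",
    "rollout",
    "rollout_batch",
    "noise_sd_from_sigma_n",
]

_LATTICE = 1e-3  # planner acceleration resolution, m/s^2
_N_COARSE = 201


class InfeasiblePlanError(RuntimeError):
    """No constant acceleration satisfies the risk cap."""


@dataclass(frozen=True)
class Plan:
    """A constant-input plan and its frozen rollout.

    The waypoints extend beyond the planning horizon (the same constant input
    continued) so that risk can be evaluated against the *planned* trajectory
    at later timesteps, until the next replan refreshes it: the driver
    evaluates risk against where they intend to be, not where execution noise
    actually put them.
    """

    a_planned: float
    a_executed: float
    created_at: float
    dt: float
    waypoints: np.ndarray   # positions at t = created_at + k*dt, k = 1..n
    velocities: np.ndarray

    @property
    def horizon(self) -> float:
        return self.waypoints.size * self.dt

    def position_at_step(self, steps_ahead: np.ndarray) -> np.ndarray:
        """Planned positions ``steps_ahead`` timesteps after creation; indices
        past the rollout end saturate at the final waypoint."""
        idx = np.minimum(steps_ahead - 1, self.waypoints.size - 1)
        return self.waypoints[idx]


@dataclass(frozen=True)
class PlannerConfig:
    v_desired: float
    a_max: float = 2.0
    noise_sd: float = 0.14
    include_resistance_in_rollout: bool = True

    def __post_init__(self) -> None:
        if self.a_max <= 0:
            raise ValueError("a_max must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def noise_sd_from_sigma_n(sigma_n: float) -> float:
    """Map the dimensionless execution-noise scale to physical units.

    The printed scale (default 140) is not in m/s^2; the executed-input noise
    is 'scaled'. The adopted mapping is sigma_n/1000 (0.14 m/s^2, plausible
    against a comfortable acceleration of 1 m/s^2). Kept in one place so the
    interpretation can be swapped without touching the planner.
    """
    return sigma_n / 1000.0


def rollout(v0: float, s0: float, a: float, n_steps: int, dt: float,
            with_resistance: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Semi-implicit Euler rollout under a constant input; returns (v, s)."""
    vs = np.empty(n_steps)
    ss = np.empty(n_steps)
    v, s = v0, s0
    for k in range(n_steps):
        drag = (0.5 + 0.005 * v * v) if with_resistance else 0.0
        v += (a - drag) * dt
        if v < 0.0:
            v = 0.0
        s += v * dt
        vs[k] = v
        ss[k] = s
    return vs, ss


def rollout_batch(v0: float, s0: float, accels: np.ndarray, n_steps: int,
                  dt: float, with_resistance: bool = True
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rollout for many candidate accelerations at once; (m, n_steps) arrays."""
    accels = np.asarray(accels, dtype=float)
    m = accels.size
    vs = np.empty((m, n_steps))
    ss = np.empty((m, n_steps))
    v = np.full(m, v0)
    s = np.full(m, s0)
    for k in range(n_steps):
        drag = 0.5 + 0.005 * v * v if with_resistance else 0.0
        v = v + (accels - drag) * dt
        np.maximum(v, 0.0, out=v)
        s = s + v * dt
        vs[:, k] = v
        ss[:, k] = s
    return vs, ss


def plan_cost(a: float, state: VehicleState, config: PlannerConfig,
              params: SimParams) -> float:
    """Comfort/speed cost of holding input ``a`` over the horizon."""
    n = params.n_plan_steps
    vs, _ = rollout(state.v, state.s, a, n, params.dt,
                    config.include_resistance_in_rollout)
    dev = vs - config.v_desired
    return float(np.dot(dev, dev) + n * a * a)


def _lattice_values(lo: float, hi: float) -> np.ndarray:
    i0 = math.ceil(round(lo / _LATTICE, 6))
    i1 = math.floor(round(hi / _LATTICE, 6))
    return np.arange(i0, i1 + 1) * _LATTICE


def _evaluate(accels: np.ndarray, state: VehicleState, config: PlannerConfig,
              params: SimParams,
              risk_fn: Callable[[np.ndarray], np.ndarray] | None,
              risk_cap: float) -> tuple[np.ndarray, np.ndarray]:
    """Costs and feasibility of candidate accelerations."""
    n = params.n_plan_steps
    vs, ss = rollout_batch(state.v, state.s, accels, n, params.dt,
                           config.include_resistance_in_rollout)
    dev = vs - config.v_desired
    costs = (dev * dev).sum(axis=1) + n * accels * accels
    if risk_fn is None or risk_cap >= 1.0:
        feasible = np.ones(accels.size, dtype=bool)
    else:
        stride = params.belief_stride
        idx = stride * np.arange(1, params.n_belief_points + 1) - 1
        risks = np.asarray(risk_fn(ss[:, idx]))
        feasible = risks <= risk_cap + 1e-12
    return costs, feasible


def optimize_plan(state: VehicleState, belief, risk_cap: float,
                  config: PlannerConfig, params: SimParams,
                  risk_fn: Callable[[np.ndarray], np.ndarray] | None = None
                  ) -> Plan:
    """Best feasible constant acceleration in [-a_max, a_max].

    ``risk_fn`` maps an array of candidate ego positions at the belief-point
    times, shape (m, n_belief_points), to the perceived risk per candidate
    (already belief-aware); ``belief`` is accepted for interface symmetry and
    may be None when ``risk_fn`` closes over it.

    Raises :class:`InfeasiblePlanError` when no candidate meets the cap.
    """
    if not 0.0 <= risk_cap <= 1.0:
        raise ValueError("risk_cap must be in [0, 1]")
    a_max = config.a_max
    coarse = np.unique(np.round(np.linspace(-a_max, a_max, _N_COARSE)
                                / _LATTICE).astype(int)) * _LATTICE
    costs, feas = _evaluate(coarse, state, config, params, risk_fn, risk_cap)

    windows: list[tuple[float, float]] = []
    if feas.any():
        best = int(np.flatnonzero(feas)[np.argmin(costs[feas])])
        step = coarse[1] - coarse[0]
        windows.append((max(coarse[best] - step, -a_max),
                        min(coarse[best] + step, a_max)))
        # refine around every feasibility boundary: the constrained optimum
        # may sit at the edge of a feasible interval between coarse nodes
        for i in np.flatnonzero(feas[:-1] != feas[1:]):
            windows.append((coarse[i], coarse[i + 1]))
        best_a = float(coarse[best])
        best_cost = float(costs[best])
    else:
        windows.append((-a_max, a_max))  # full lattice sweep before giving up
        best_a = None
        best_cost = math.inf

    fine = np.unique(np.concatenate([_lattice_values(lo, hi)
                                     for lo, hi in windows]))
    fine = fine[(fine >= -a_max - 1e-12) & (fine <= a_max + 1e-12)]
    costs_f, feas_f = _evaluate(fine, state, config, params, risk_fn, risk_cap)
    if feas_f.any():
        j = int(np.flatnonzero(feas_f)[np.argmin(costs_f[feas_f])])
        if costs_f[j] < best_cost:
            best_a, best_cost = float(fine[j]), float(costs_f[j])
    if best_a is None:
        raise InfeasiblePlanError(
            f"no feasible constant acceleration for risk cap {risk_cap:.4g}")

    vs, ss = rollout(state.v, state.s, best_a, 2 * params.n_plan_steps,
                     params.dt, config.include_resistance_in_rollout)
    return Plan(a_planned=best_a, a_executed=best_a, created_at=state.t,
                dt=params.dt, waypoints=ss, velocities=vs)


def fallback_plan(state: VehicleState, other_position: float,
                  config: PlannerConfig, params: SimParams) -> Plan:
    """Full braking if behind the other vehicle (ties brake), else full
    acceleration; used when the constrained optimisation is infeasible."""
    a = -config.a_max if state.s <= other_position else config.a_max
    vs, ss = rollout(state.v, state.s, a, 2 * params.n_plan_steps, params.dt,
                     config.include_resistance_in_rollout)
    return Plan(a_planned=a, a_executed=a, created_at=state.t, dt=params.dt,
                waypoints=ss, velocities=vs)


def perturb_plan(plan: Plan, noise_sd: float,
                 rng: np.random.Generator | None = None) -> Plan:
    """Add frozen execution noise: one draw per replan, constant until the next.

    Only the executed input changes; the planned trajectory (used for risk
    evaluation) is untouched.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0.0:
        return plan
    if rng is None:
        raise ValueError("rng required when noise_sd > 0")
    eps = rng.normal(0.0, noise_sd)
    return replace(plan, a_executed=plan.a_planned + eps)
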