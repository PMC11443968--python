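"""The replanning state machine per driver and the coupled two-agent trial loop.

Each driver holds exactly one active plan after control onset and touches it
only when a trigger fires:

* **upper** — the perceived risk exceeds the (dynamic) upper threshold; the
  driver replans with the risk capped at ``0.8 * rho_l``;
* **relax** — the risk has stayed below the lower threshold continuously for
  the saturation time ``tau``; the conflict is considered resolved and the
  driver replans with the risk capped at ``0.6 * rho_u``;
* **vd_reached** — the vehicle crosses its desired velocity while a nonzero
  input is applied; the driver replans to hold the preferred speed.

If a constrained replan is infeasible the driver falls back to full braking
(when behind) or full acceleration (when ahead) and retries the optimisation
every following step. Both drivers update synchronously from the previous
timestep's public states, so neither has a within-step information advantage.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib

import numpy as np

from . import metrics as _metrics
from .perception import (AccelerationMemory, PerceptionState, project_belief,
                         update_perceived_velocity)
from .planner import (InfeasiblePlanError, Plan, PlannerConfig, fallback_plan,
                      noise_sd_from_sigma_n, optimize_plan, perturb_plan)
from .records import DriverTrace, TrialRecord
from .risk import RiskThresholds, dynamic_thresholds, plan_positions_risk
from .scenario import (Condition, SimParams, TrackGeometry, VehicleState,
                       detect_collision, initial_states, resistance,
                       step_vehicle)

__all__ = [
    "DriverAgent",
    "ConstantVelocityAgent",
    "simulate_trial",
    "run_trial",
    "run_batch",
    "records_to_csv",
    "batch_summary_json",
    "trial_seed",
]

_MAX_DURATION = 60.0  # hard safety cap, s
_VD_BAND = 0.01  # m/s, desired-velocity crossing tolerance


class ConstantVelocityAgent:
    """Ghost opponent that holds its velocity exactly (used in calibration)."""

    def __init__(self, side: str):
        self.side = side

    def control(self, own: VehicleState, other_s: float, other_v: float,
                other_a: float, t: float, in_tunnel: bool):
        if in_tunnel:
            return 0.0, "none", 0.0, math.nan, math.nan
        return resistance(own.v), "none", 0.0, math.nan, math.nan


class DriverAgent:
    """One model driver: perception, belief, plan, and threshold state machine."""

    def __init__(self, side: str, thresholds: RiskThresholds,
                 params: SimParams, geometry: TrackGeometry,
                 config: PlannerConfig,
                 rng: np.random.Generator | None = None):
        self.side = side
        self.thresholds = thresholds
        self.params = params
        self.geometry = geometry
        self.config = config
        self.rng = rng
        if rng is None and (params.beta != 0.0 or config.noise_sd != 0.0):
            raise ValueError("rng required when perception or execution noise is on")

        self.v_perceived: float | None = None
        self.memory = AccelerationMemory(params.memory_size)
        self.memory.append(0.0)  # warm-up seed: assume steady motion
        self.plan: Plan | None = None
        self.below_lower_since: float | None = None
        self.in_fallback = False
        self.fallback_trigger = "upper"
        self._prev_dev: float | None = None
        # belief-time subsampling of the plan rollout
        self._belief_idx = (params.belief_stride
                            * np.arange(1, params.n_belief_points + 1) - 1)

    # -- perception ---------------------------------------------------------

    def _perceive(self, other_s: float, other_v: float, other_a: float
                  ) -> PerceptionState:
        if self.v_perceived is None:
            self.v_perceived = other_v  # initialised at the true velocity
        else:
            self.v_perceived = update_perceived_velocity(
                self.v_perceived, other_v, self.params.alpha,
                self.params.beta, self.params.dt, self.rng)
        self.memory.append(other_a)
        return PerceptionState(v_perceived=self.v_perceived,
                               observed_position=other_s,
                               observed_acceleration=other_a)

    # -- planning -----------------------------------------------------------

    def _positions_at_belief_times(self, t: float) -> np.ndarray:
        """Ego positions of the *frozen* planned trajectory at the current
        belief-point times. The plan is not re-anchored to the actual state
        between replans, so execution-noise drift goes unnoticed by the
        driver until the next replan."""
        offset = int(round((t - self.plan.created_at) / self.params.dt))
        return self.plan.position_at_step(offset + self._belief_idx + 1)

    def _replan(self, own: VehicleState, other_s: float, belief, cap: float,
                trigger: str) -> str:
        agg = self.params.risk_aggregation

        def risk_fn(positions):
            return plan_positions_risk(positions, belief, self.geometry, agg)

        try:
            plan = optimize_plan(own, belief, cap, self.config, self.params,
                                 risk_fn)
        except InfeasiblePlanError:
            self.plan = fallback_plan(own, other_s, self.config, self.params)
            self.in_fallback = True
            self.fallback_trigger = trigger
            return "fallback"
        self.plan = perturb_plan(plan, self.config.noise_sd, self.rng)
        self.in_fallback = False
        return trigger

    def _cap_for(self, trigger: str, rho_l: float, rho_u: float) -> float:
        if trigger == "upper":
            return 0.8 * rho_l
        if trigger == "relax":
            return 0.6 * rho_u
        return 1.0

    # -- main step ----------------------------------------------------------

    def control(self, own: VehicleState, other_s: float, other_v: float,
                other_a: float, t: float, in_tunnel: bool):
        """Observe, update belief and risk, maybe replan; return the executed
        input plus (event, risk, rho_l, rho_u) diagnostics."""
        obs = self._perceive(other_s, other_v, other_a)
        if in_tunnel:
            return 0.0, "none", 0.0, math.nan, math.nan

        params = self.params
        belief = project_belief(obs, self.memory, params, t0=t)
        event = "none"
        if self.plan is None:
            # control onset: unconstrained plan so the first risk evaluation
            # has a concrete trajectory to work with
            event = self._replan(own, other_s, belief, 1.0, "initial")

        positions = self._positions_at_belief_times(t)
        risk = float(plan_positions_risk(positions, belief, self.geometry,
                                         params.risk_aggregation))
        delta_p = own.s - other_s
        delta_v = own.v - self.v_perceived
        rho_l, rho_u = dynamic_thresholds(self.thresholds, delta_p, delta_v)

        # saturation timer: first instant of sub-rho_l risk; any instant at
        # or above rho_l clears it
        if risk < rho_l:
            if self.below_lower_since is None:
                self.below_lower_since = t
        else:
            self.below_lower_since = None

        dev = own.v - self.config.v_desired
        crossed_vd = (self._prev_dev is not None
                      and (self._prev_dev * dev < 0.0
                           or (abs(dev) < _VD_BAND <= abs(self._prev_dev))))
        self._prev_dev = dev

        if event == "none":
            if self.in_fallback:
                # retry the failed optimisation every step until feasible
                if risk > rho_u:
                    self.fallback_trigger = "upper"
                cap = self._cap_for(self.fallback_trigger, rho_l, rho_u)
                event = self._replan(own, other_s, belief, cap,
                                     self.fallback_trigger)
            elif risk > rho_u:
                event = self._replan(own, other_s, belief, 0.8 * rho_l,
                                     "upper")
            elif (self.below_lower_since is not None
                  and t - self.below_lower_since >= params.tau - 1e-9):
                event = self._replan(own, other_s, belief, 0.6 * rho_u,
                                     "relax")
                self.below_lower_since = None
            elif crossed_vd and self.plan.a_executed != 0.0:
                event = self._replan(own, other_s, belief, 1.0, "vd_reached")

        if event != "none":
            # log the risk the driver ends the step with
            risk = float(plan_positions_risk(
                self.plan.waypoints[self._belief_idx], belief, self.geometry,
                params.risk_aggregation))
        return self.plan.a_executed, event, risk, rho_l, rho_u


# -- trial and batch drivers -------------------------------------------------


_TRACE_KEYS = ("s", "v", "a_input", "risk", "rho_u", "rho_l", "event")


def simulate_trial(condition: Condition, left_agent, right_agent,
                   geometry: TrackGeometry, params: SimParams,
                   condition_label: str | None = None, pair_id: int = 0,
                   repetition: int = 0, seed: int = 0,
                   max_duration: float = _MAX_DURATION) -> TrialRecord:
    """Run one closed-loop trial with two (arbitrary) agents.

    The trial starts inside the tunnel (perception active, no control) and
    ends when both front bumpers pass the end of the track, on collision, or
    at the hard duration cap.
    """
    dt = params.dt
    state_l, state_r = initial_states(condition, geometry)
    v0 = {"left": state_l.v, "right": state_r.v}
    prev_v = {"left": state_l.v, "right": state_r.v}
    onset: dict[str, float | None] = {"left": None, "right": None}

    logs = {side: {k: [] for k in _TRACE_KEYS} for side in ("left", "right")}
    ts: list[float] = []

    agents = {"left": left_agent, "right": right_agent}
    states = {"left": state_l, "right": state_r}
    t = 0.0
    collision = False
    n_max = int(round(max_duration / dt))

    for _ in range(n_max):
        inputs = {}
        accel_obs = {s: (states[s].v - prev_v[s]) / dt for s in states}
        for side, other in (("left", "right"), ("right", "left")):
            own = states[side]
            in_tunnel = own.s <= geometry.tunnel_length
            if not in_tunnel and onset[side] is None:
                onset[side] = t
            a, event, risk, rho_l, rho_u = agents[side].control(
                own, states[other].s, states[other].v, accel_obs[other],
                t, in_tunnel)
            inputs[side] = (a, in_tunnel)
            lg = logs[side]
            lg["s"].append(own.s)
            lg["v"].append(own.v)
            lg["a_input"].append(0.0 if in_tunnel else a)
            lg["risk"].append(risk)
            lg["rho_u"].append(rho_u)
            lg["rho_l"].append(rho_l)
            lg["event"].append(event)
        ts.append(t)

        prev_v = {s: states[s].v for s in states}
        for side in states:
            a, in_tunnel = inputs[side]
            states[side] = step_vehicle(states[side], a, dt, in_tunnel)
        t = round(t + dt, 9)

        if detect_collision(states["left"].s, states["right"].s, geometry):
            collision = True
            break
        if min(states["left"].s, states["right"].s) > geometry.track_length:
            break

    # terminal row
    for side in states:
        lg = logs[side]
        lg["s"].append(states[side].s)
        lg["v"].append(states[side].v)
        lg["a_input"].append(0.0)
        lg["risk"].append(math.nan)
        lg["rho_u"].append(math.nan)
        lg["rho_l"].append(math.nan)
        lg["event"].append("none")
    ts.append(t)

    traces = {}
    for side in ("left", "right"):
        lg = logs[side]
        traces[side] = DriverTrace(
            s=np.asarray(lg["s"]), v=np.asarray(lg["v"]),
            a_input=np.asarray(lg["a_input"]), risk=np.asarray(lg["risk"]),
            rho_u=np.asarray(lg["rho_u"]), rho_l=np.asarray(lg["rho_l"]),
            event=lg["event"], v_initial=v0[side],
            control_onset=onset[side])

    record = TrialRecord(
        condition_label=condition_label or condition.label,
        pair_id=pair_id, repetition=repetition, seed=seed, dt=dt,
        t=np.asarray(ts), left=traces["left"], right=traces["right"])

    outcome = {"collision": collision, "duration": t}
    if not collision:
        try:
            outcome["merge_gap"] = _metrics.merge_gap(record, geometry)
        except ValueError:
            outcome["merge_gap"] = math.nan
    else:
        outcome["merge_gap"] = math.nan
    try:
        outcome["who_first"] = _metrics.who_first(record, geometry)
    except ValueError:
        outcome["who_first"] = "none"
    record.outcome = outcome
    return record


def trial_seed(base_seed: int, pair_id: int, condition_label: str,
               repetition: int) -> np.random.SeedSequence:
    """Deterministic per-trial seed so any single trial reproduces in isolation."""
    label_hash = zlib.crc32(condition_label.encode("utf-8"))
    return np.random.SeedSequence([base_seed, pair_id, label_hash, repetition])


def run_trial(condition: Condition | str,
              pair: tuple[RiskThresholds, RiskThresholds],
              geometry: TrackGeometry | None = None,
              params: SimParams | None = None,
              seed: int = 0, noise: bool = True,
              pair_id: int = 0, repetition: int = 0) -> TrialRecord:
    """Run one dyadic trial between two model drivers.

    ``noise=False`` disables both perception and execution noise (a fully
    deterministic trial). Identical seeds yield bit-identical records.
    """
    geometry = geometry or TrackGeometry()
    params = params or SimParams()
    if isinstance(condition, str):
        condition = Condition.from_label(condition)
    if not noise:
        params = dataclasses.replace(params, beta=0.0, sigma_n=0.0)

    ss = trial_seed(seed, pair_id, condition.label, repetition)
    rng_l, rng_r = (np.random.default_rng(s) for s in ss.spawn(2))
    states = initial_states(condition, geometry)
    agents = []
    for side, thresholds, state, rng in (("left", pair[0], states[0], rng_l),
                                         ("right", pair[1], states[1], rng_r)):
        cfg = PlannerConfig(v_desired=params.v_desired or state.v,
                            a_max=params.a_max,
                            noise_sd=noise_sd_from_sigma_n(params.sigma_n))
        agents.append(DriverAgent(side, thresholds, params, geometry, cfg,
                                  rng if noise else None))
    return simulate_trial(condition, agents[0], agents[1], geometry, params,
                          pair_id=pair_id, repetition=repetition, seed=seed)


def run_batch(pairs: list[tuple[RiskThresholds, RiskThresholds]],
              conditions: list[Condition] | None = None,
              repetitions: int = 10, base_seed: int = 0,
              geometry: TrackGeometry | None = None,
              params: SimParams | None = None, noise: bool = True,
              trials_csv=None, summary_json=None,
              progress: bool = False) -> list[TrialRecord]:
    """Run the full campaign: every pair x condition x repetition.

    Per-trial seeds are derived from (base_seed, pair, condition, repetition),
    so the batch is reproducible and any one trial can be re-run alone.
    """
    from .scenario import default_condition_set
    conditions = conditions if conditions is not None else default_condition_set()
    records = []
    for pair_id, pair in enumerate(pairs):
        for condition in conditions:
            for rep in range(repetitions):
                records.append(run_trial(condition, pair, geometry, params,
                                         seed=base_seed, noise=noise,
                                         pair_id=pair_id, repetition=rep))
        if progress:
            print(f"pair {pair_id + 1}/{len(pairs)} done "
                  f"({len(records)} trials)")
    if trials_csv is not None:
        records_to_csv(records, trials_csv)
    if summary_json is not None:
        batch_summary_json(records, summary_json)
    return records


def records_to_csv(records: list[TrialRecord], path) -> None:
    """Concatenate all per-timestep rows of a batch into one CSV."""
    import pandas as pd
    pd.concat([r.to_dataframe() for r in records],
              ignore_index=True).to_csv(path, index=False)


def batch_summary_json(records: list[TrialRecord], path) -> None:
    """Per-trial outcome summary (one JSON object per trial)."""
    rows = []
    for r in records:
        out = dict(r.outcome)
        out.update(condition=r.condition_label, pair=r.pair_id,
                   repetition=r.repetition, seed=r.seed)
        rows.append(out)
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1, default=float)
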