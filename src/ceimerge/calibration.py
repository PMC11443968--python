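"""Threshold calibration: grid search, trial matching, mixed-effects pooling.

Because control is intermittent, a single trial carries little information
about a driver's risk thresholds — the driver either acted (threshold
exceeded) or did not. The calibration pipeline therefore:

1. builds, per kinematic condition, a 25x25 grid of (theta_l, theta_u) base
   thresholds and simulates one deterministic trial per cell — a single model
   driver against a constant-velocity opponent, all noise and incentive
   functions disabled — recording the driver's velocity deviation from the
   initial velocity 1.0 s after control onset;
2. matches every observed trial-level deviation to the grid cell whose
   deviation is closest, yielding per-trial threshold estimates;
3. pools the trial-level estimates with two linear mixed-effects models
   (``theta ~ dp * dv`` with a random intercept per participant): the fixed
   slopes become the population incentive coefficients and the intercept plus
   each random effect becomes the participant's base threshold.

A synthetic-participant generator stands in for the human dataset so the
pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .planner import PlannerConfig, noise_sd_from_sigma_n
from .risk import RiskThresholds
from .scenario import (Condition, SimParams, TrackGeometry,
                       default_condition_set, initial_states,
                       mirror_condition)
from .simulation import ConstantVelocityAgent, DriverAgent, simulate_trial

__all__ = [
    "GridSpec",
    "TrialThresholdEstimate",
    "IncentiveFit",
    "build_grid",
    "single_driver_response",
    "grid_response_lookup",
    "match_trial_thresholds",
    "fit_incentive",
    "synth_participants",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform threshold grid: n x n cells over the stated ranges."""

    upper_range: tuple[float, float] = (0.3, 0.9)
    lower_range: tuple[float, float] = (0.01, 0.4)
    n: int = 25

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def upper_values(self) -> np.ndarray:
        return np.linspace(*self.upper_range, self.n)

    @property
    def lower_values(self) -> np.ndarray:
        return np.linspace(*self.lower_range, self.n)


@dataclass(frozen=True)
class TrialThresholdEstimate:
    participant: int
    condition: str
    theta_l: float
    theta_u: float
    observed_deviation: float


def build_grid(spec: GridSpec | None = None) -> list[tuple[float, float]]:
    """All n^2 (theta_l, theta_u) cells, lower axis fastest.

    Cells with theta_l >= theta_u are part of the grid but cannot be
    simulated as valid agents; the response lookup marks them NaN.
    """
    spec = spec or GridSpec()
    return [(float(tl), float(tu))
            for tu in spec.upper_values for tl in spec.lower_values]


def _control_onset_step(s0: float, v0: float, tunnel_length: float,
                        dt: float) -> int:
    """First timestep index at which the front bumper is strictly past the
    tunnel exit (constant velocity inside the tunnel)."""
    k = math.floor((tunnel_length - s0) / (v0 * dt))
    while s0 + v0 * k * dt <= tunnel_length:
        k += 1
    return max(k, 0)


def single_driver_response(condition: Condition, theta_l: float,
                           theta_u: float,
                           params: SimParams | None = None,
                           geometry: TrackGeometry | None = None,
                           side: str = "left", noise: bool = False,
                           rng: np.random.Generator | None = None,
                           horizon: float = 1.0) -> float:
    """Velocity deviation of one model driver ``horizon`` seconds after its
    control onset, against a constant-velocity opponent.

    ``condition`` is given from the driver's own perspective; for a right
    driver the scene is mirrored so the model driver always occupies the left
    road. Incentive functions are off (base thresholds only).
    """
    params = params or SimParams()
    geometry = geometry or TrackGeometry()
    if not noise:
        import dataclasses
        params = dataclasses.replace(params, beta=0.0, sigma_n=0.0)
    if side == "right":
        condition = mirror_condition(condition)
    elif side != "left":
        raise ValueError(f"unknown side {side!r}")

    thresholds = RiskThresholds(theta_l, theta_u)  # lambdas zero: incentives off
    state_l, _ = initial_states(condition, geometry)
    onset_k = _control_onset_step(state_l.s, state_l.v,
                                  geometry.tunnel_length, params.dt)
    n_horizon = round(horizon / params.dt)
    stop_at = (onset_k + n_horizon + 1) * params.dt

    cfg = PlannerConfig(v_desired=params.v_desired or state_l.v,
                        a_max=params.a_max,
                        noise_sd=noise_sd_from_sigma_n(params.sigma_n))
    agent = DriverAgent("left", thresholds, params, geometry, cfg,
                        rng if noise else None)
    record = simulate_trial(condition, agent, ConstantVelocityAgent("right"),
                            geometry, params, max_duration=stop_at)
    idx = onset_k + n_horizon
    if idx >= record.left.v.size:
        raise RuntimeError("trial ended before the response horizon")
    return float(record.left.v[idx] - record.left.v_initial)


def grid_response_lookup(condition: Condition,
                         grid: list[tuple[float, float]] | None = None,
                         params: SimParams | None = None,
                         geometry: TrackGeometry | None = None,
                         side: str = "left") -> pd.DataFrame:
    """Deterministic deviation-at-1.0 s response per grid cell.

    Returns a DataFrame with columns theta_l, theta_u, deviation; invalid
    cells (theta_l >= theta_u) carry NaN deviations.
    """
    grid = grid if grid is not None else build_grid()
    rows = []
    for theta_l, theta_u in grid:
        if theta_l >= theta_u:
            dev = math.nan
        else:
            dev = single_driver_response(condition, theta_l, theta_u,
                                         params, geometry, side=side)
        rows.append((theta_l, theta_u, dev))
    return pd.DataFrame(rows, columns=["theta_l", "theta_u", "deviation"])


def match_trial_thresholds(observed_deviation: float,
                           lookup: pd.DataFrame,
                           signed: bool = True) -> tuple[float, float]:
    """Grid cell whose simulated deviation best matches an observed one.

    Ties (within 1e-12) are broken toward the most passive explanation:
    largest theta_u, then largest theta_l. ``signed=False`` matches absolute
    deviations instead.
    """
    valid = lookup.dropna(subset=["deviation"])
    if valid.empty:
        raise ValueError("lookup contains no valid cells")
    if signed:
        diffs = (valid.deviation - observed_deviation).abs()
    else:
        diffs = (valid.deviation.abs() - abs(observed_deviation)).abs()
    best = diffs.min()
    cand = valid[diffs <= best + 1e-12]
    cand = cand.sort_values(["theta_u", "theta_l"], ascending=False)
    row = cand.iloc[0]
    return float(row.theta_l), float(row.theta_u)


@dataclass
class IncentiveFit:
    """Result of the mixed-effects pooling stage."""

    lambda_u: tuple[float, float, float]
    lambda_l: tuple[float, float, float]
    se_u: tuple[float, float, float]
    se_l: tuple[float, float, float]
    participant_thetas: pd.DataFrame  # participant, theta_l, theta_u
    results: dict = field(default_factory=dict, repr=False)


def _fit_one(data: pd.DataFrame, response: str):
    import statsmodels.formula.api as smf

    model = smf.mixedlm(f"{response} ~ dp * dv", data,
                        groups=data["participant"])
    try:
        res = model.fit(reml=True)
    except Exception as exc:  # singular fits are reported, not hidden
        raise RuntimeError(
            f"mixed-effects fit for {response} failed: {exc}") from exc
    fe = res.fe_params
    se = res.bse_fe
    lambdas = (float(fe["dp"]), float(fe["dv"]), float(fe["dp:dv"]))
    ses = (float(se["dp"]), float(se["dv"]), float(se["dp:dv"]))
    intercept = float(fe["Intercept"])
    thetas = {g: intercept + float(np.asarray(re_).ravel()[0])
              for g, re_ in res.random_effects.items()}
    return lambdas, ses, thetas, res


def fit_incentive(estimates: pd.DataFrame) -> IncentiveFit:
    """Pool trial-level threshold estimates into population incentives and
    participant base values.

    ``estimates`` needs columns participant, dp, dv, theta_l, theta_u, where
    dp/dv are the condition's projected headway and relative velocity from
    the participant's own perspective.
    """
    required = {"participant", "dp", "dv", "theta_l", "theta_u"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates missing columns: {sorted(missing)}")
    if estimates.participant.nunique() < 2:
        raise ValueError("need at least two participants")
    if estimates.groupby(["dp", "dv"]).ngroups < 2:
        raise ValueError("need at least two distinct conditions")
    if estimates.dp.nunique() < 2 or estimates.dv.nunique() < 2:
        raise ValueError(
            "both dp and dv must vary across conditions; a constant "
            "covariate makes the dp*dv design singular")

    lam_u, se_u, th_u, res_u = _fit_one(estimates, "theta_u")
    lam_l, se_l, th_l, res_l = _fit_one(estimates, "theta_l")
    participants = sorted(estimates.participant.unique())
    thetas = pd.DataFrame({
        "participant": participants,
        "theta_l": [th_l[p] for p in participants],
        "theta_u": [th_u[p] for p in participants],
    })
    return IncentiveFit(lambda_u=lam_u, lambda_l=lam_l, se_u=se_u, se_l=se_l,
                        participant_thetas=thetas,
                        results={"upper": res_u, "lower": res_l})


def synth_participants(true_thetas: list[tuple[float, float]],
                       conditions: list[Condition] | None = None,
                       reps: int = 10, seed: int = 0, noise: bool = False,
                       params: SimParams | None = None,
                       geometry: TrackGeometry | None = None) -> pd.DataFrame:
    """Trial-level deviation observations from simulated participants.

    Each participant is a model driver with known (theta_l, theta_u),
    simulated against a constant-velocity opponent in every condition x
    repetition; participants alternate left/right sides as in a paired
    experiment. With ``noise=False`` the repetitions of a condition are
    identical; with noise on, perception and execution noise make them vary.
    Output columns: participant, side, condition, rep, deviation_at_1s.
    """
    conditions = conditions if conditions is not None else default_condition_set()
    ss = np.random.SeedSequence(seed)
    rows = []
    for pid, (theta_l, theta_u) in enumerate(true_thetas):
        side = "left" if pid % 2 == 0 else "right"
        for cond in conditions:
            base_dev = None
            for rep in range(reps):
                if noise:
                    label_hash = zlib.crc32(cond.label.encode("utf-8"))
                    rng = np.random.default_rng(
                        np.random.SeedSequence([seed, pid, label_hash, rep]))
                    dev = single_driver_response(cond, theta_l, theta_u,
                                                 params, geometry, side=side,
                                                 noise=True, rng=rng)
                else:
                    if base_dev is None:
                        base_dev = single_driver_response(
                            cond, theta_l, theta_u, params, geometry,
                            side=side)
                    dev = base_dev
                rows.append((pid, side, cond.label, rep, dev))
    return pd.DataFrame(rows, columns=["participant", "side", "condition",
                                       "rep", "deviation_at_1s"])


def calibrate_thresholds(deviations: pd.DataFrame,
                         grid: list[tuple[float, float]] | None = None,
                         params: SimParams | None = None,
                         geometry: TrackGeometry | None = None,
                         signed: bool = True) -> tuple[pd.DataFrame, IncentiveFit]:
    """Full pipeline: grid lookups, per-trial matching, mixed-effects pooling.

    ``deviations`` has columns participant, side, condition, rep,
    deviation_at_1s. Returns (trial-level estimates, pooled fit). Condition
    covariates enter from each driver's perspective (sign-flipped for right
    drivers).
    """
    grid = grid if grid is not None else build_grid()
    lookups: dict[tuple[str, str], pd.DataFrame] = {}
    est_rows = []
    for (cond_label, side), group in deviations.groupby(["condition", "side"]):
        cond = Condition.from_label(cond_label)
        key = (cond_label, side)
        if key not in lookups:
            lookups[key] = grid_response_lookup(cond, grid, params, geometry,
                                                side=side)
        lut = lookups[key]
        sign = 1.0 if side == "left" else -1.0
        dp = sign * cond.projected_headway
        dv = sign * cond.relative_velocity
        for _, row in group.iterrows():
            tl, tu = match_trial_thresholds(row.deviation_at_1s, lut,
                                            signed=signed)
            est_rows.append((int(row.participant), cond_label, dp, dv,
                             tl, tu, float(row.deviation_at_1s)))
    estimates = pd.DataFrame(est_rows, columns=[
        "participant", "condition", "dp", "dv", "theta_l", "theta_u",
        "observed_deviation"])
    fit = fit_incentive(estimates)
    return estimates, fit
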