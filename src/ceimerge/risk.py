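"""Perceived collision risk and dynamic risk thresholds.

For every belief point the driver determines the interval of other-vehicle
positions that would collide with the ego's planned position at that time
(possible only within one vehicle length of the merge point, where the two
roads share a corridor). The believed probability of the other vehicle lying
inside those bounds is the per-point collision probability; the perceived
risk aggregates the per-point probabilities over the horizon (maximum by
default).

The risk is compared against two personal thresholds whose base values are
shifted by an incentive function, linear in the relative position and
velocity from the driver's own perspective — encoding, e.g., that the
following driver has more reason to act.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perception import Belief, mixture_interval_probability
from .scenario import TrackGeometry

__all__ = [
    "RiskThresholds",
    "RiskSignal",
    "collision_bounds",
    "perceived_risk",
    "plan_positions_risk",
    "dynamic_thresholds",
]

_CLAMP_EPS = 1e-6

#: domain on which the incentive coefficients were calibrated (condition-level
#: projected headway [m] and relative velocity [m/s]); the linear incentive
#: model is not extrapolated beyond it
INCENTIVE_DP_RANGE = (-4.0, 4.0)
INCENTIVE_DV_RANGE = (-0.8, 0.8)


@dataclass(frozen=True)
class RiskThresholds:
    """Per-driver base thresholds plus population incentive coefficients.

    ``theta_l`` / ``theta_u`` are the base lower/upper risk thresholds;
    ``lambda_u`` and ``lambda_l`` are the (delta_p, delta_v, delta_p*delta_v)
    incentive coefficients. Setting all lambdas to zero recovers the
    static-threshold variant.
    """

    theta_l: float
    theta_u: float
    lambda_u: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lambda_l: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_l < self.theta_u < 1.0:
            raise ValueError("need 0 < theta_l < theta_u < 1")


@dataclass(frozen=True)
class RiskSignal:
    risk: float
    per_point: np.ndarray
    rho_l: float | None = None
    rho_u: float | None = None


def collision_bounds(ego_position: float,
                     geometry: TrackGeometry) -> tuple[float, float] | None:
    """Other-vehicle position interval that collides with the ego at this time.

    Returns None while the ego front bumper is still at least a vehicle
    length before the merge point (the roads are separate corridors there).
    """
    L = geometry.vehicle_length
    boundary = geometry.merge_point - L
    if ego_position <= boundary:
        return None
    return max(ego_position - L, boundary), ego_position + L


def _aggregate(per_point: np.ndarray, mode: str) -> float:
    if mode == "sum":
        return float(min(per_point.sum(), 1.0))
    return float(per_point.max()) if per_point.size else 0.0


def plan_positions_risk(positions: np.ndarray, belief: Belief,
                        geometry: TrackGeometry,
                        aggregation: str = "max") -> np.ndarray:
    """Risk of one or many candidate ego trajectories against a belief.

    ``positions``: array (..., n_belief_points) of ego front-bumper positions
    at the belief-point times. Returns the aggregated risk per candidate.
    """
    positions = np.asarray(positions, dtype=float)
    L = geometry.vehicle_length
    boundary = geometry.merge_point - L
    lo = np.maximum(positions - L, boundary)
    hi = positions + L
    probs = mixture_interval_probability(belief.mus, belief.sigmas,
                                         belief.phi, lo, hi)
    probs = np.where(positions > boundary, probs, 0.0)
    if aggregation == "sum":
        return np.minimum(probs.sum(axis=-1), 1.0)
    return probs.max(axis=-1)


def perceived_risk(plan, belief: Belief, geometry: TrackGeometry,
                   aggregation: str = "max") -> RiskSignal:
    """Perceived collision probability of an ego plan given the belief.

    The plan's waypoints are interpolated at the belief-point times; per
    point, the probability that the other vehicle lies within the collision
    bounds of the interpolated ego position is computed, and the per-point
    probabilities are aggregated (max by default, or sum capped at 1).
    """
    way_times = plan.created_at + np.arange(1, plan.waypoints.size + 1) * plan.dt
    times = belief.t0 + belief.offsets
    ego_pos = np.interp(times, way_times, plan.waypoints)
    L = geometry.vehicle_length
    boundary = geometry.merge_point - L
    lo = np.maximum(ego_pos - L, boundary)
    hi = ego_pos + L
    per_point = mixture_interval_probability(belief.mus, belief.sigmas,
                                             belief.phi, lo, hi)
    per_point = np.where(ego_pos > boundary, per_point, 0.0)
    return RiskSignal(risk=_aggregate(per_point, aggregation),
                      per_point=per_point)


def dynamic_thresholds(thresholds: RiskThresholds, delta_p: float,
                       delta_v: float,
                       dp_range: tuple[float, float] = INCENTIVE_DP_RANGE,
                       dv_range: tuple[float, float] = INCENTIVE_DV_RANGE
                       ) -> tuple[float, float]:
    """Current (rho_l, rho_u) after the incentive adjustment.

    rho = theta + l1*delta_p + l2*delta_v + l3*delta_p*delta_v, per driver
    perspective (delta_p = s_ego - s_other, delta_v = v_ego - v_other).

    The incentive inputs are clamped to the domain the coefficients were
    calibrated on (conditions span +-4 m and +-0.8 m/s): once an interaction
    resolves, the raw relative position grows without bound and the linear
    terms would otherwise drive both thresholds to their guards, leaving the
    driver unable to trigger any further replan. The results are additionally
    clamped into (0, 1) with rho_l < rho_u enforced.
    """
    lu1, lu2, lu3 = thresholds.lambda_u
    ll1, ll2, ll3 = thresholds.lambda_l
    delta_p = min(max(delta_p, dp_range[0]), dp_range[1])
    delta_v = min(max(delta_v, dv_range[0]), dv_range[1])
    inter = delta_p * delta_v
    rho_u = thresholds.theta_u + lu1 * delta_p + lu2 * delta_v + lu3 * inter
    rho_l = thresholds.theta_l + ll1 * delta_p + ll2 * delta_v + ll3 * inter
    rho_u = min(max(rho_u, _CLAMP_EPS), 1.0 - _CLAMP_EPS)
    rho_l = min(max(rho_l, _CLAMP_EPS), 1.0 - _CLAMP_EPS)
    if rho_l >= rho_u:
        rho_l = rho_u - _CLAMP_EPS
    return rho_l, rho_u
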