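"""Track geometry, vehicle dynamics, and kinematic condition construction.

The scenario is a simplified merge: two straight approach roads of equal
length join at a single merge point, followed by a car-following section.
Each vehicle is a point mass with velocity-dependent rolling/air resistance;
vehicle dimensions matter only for collision detection. A *condition* is a
kinematic cell defined by the projected front-to-front headway the vehicles
would have at the merge point under constant initial velocities, and their
initial relative velocity. Positive values favour the left driver.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TrackGeometry",
    "VehicleState",
    "Condition",
    "SimParams",
    "resistance",
    "step_vehicle",
    "default_condition_set",
    "initial_states",
    "detect_collision",
    "mirror_condition",
]


@dataclass(frozen=True)
class TrackGeometry:
    """Along-track layout; all coordinates in metres.

    The track has three sections: tunnel, approach, and follow. The merge
    point sits at the end of the approach section. Vehicles may start at
    negative positions (conceptually deeper inside the tunnel) so that any
    condition is realisable.
    """

    tunnel_length: float = 50.0
    approach_length: float = 50.0
    follow_length: float = 50.0
    vehicle_length: float = 4.5
    vehicle_width: float = 1.8

    def __post_init__(self) -> None:
        for name in ("tunnel_length", "approach_length", "follow_length",
                     "vehicle_length", "vehicle_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def merge_point(self) -> float:
        return self.tunnel_length + self.approach_length

    @property
    def track_length(self) -> float:
        return self.tunnel_length + self.approach_length + self.follow_length


@dataclass(frozen=True)
class VehicleState:
    """Point-mass state: front-bumper position s, velocity v, applied input."""

    s: float
    v: float
    a_input: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("vehicle velocity must be non-negative")


def _fmt_num(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class Condition:
    """One kinematic cell: projected headway [m] and relative velocity [m/s].

    The label convention is ``<headway>_<relative velocity x 10>``, e.g.
    ``"4_-8"`` for a 4 m projected headway advantage and a 0.8 m/s velocity
    disadvantage for the left driver.
    """

    projected_headway: float
    relative_velocity: float

    @property
    def label(self) -> str:
        return f"{_fmt_num(self.projected_headway)}_{_fmt_num(self.relative_velocity * 10)}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        head, _, rv = label.rpartition("_")
        if not head:
            raise ValueError(f"malformed condition label: {label!r}")
        return cls(float(head), float(rv) / 10.0)


def mirror_condition(condition: Condition) -> Condition:
    """The same scenario seen with left and right swapped."""
    return Condition(-condition.projected_headway, -condition.relative_velocity)


@dataclass(frozen=True)
class SimParams:
    """Fixed model and simulation parameters.

    Defaults are the manually designed values used throughout: planning
    horizon T, timestep dt, acceleration-memory span Tm, belief frequency fb,
    execution-noise scale sigma_n (dimensionless as printed; see
    :func:`ceimerge.planner.noise_sd_from_sigma_n`), velocity-perception
    noise level beta, saturation time tau, belief variance scaling phi,
    perception update rate alpha, and comfortable acceleration ac.
    """

    dt: float = 0.05
    T: float = 6.0
    Tm: float = 4.0
    fb: float = 4.0
    sigma_n: float = 140.0
    beta: float = 0.6
    tau: float = 1.6
    phi: float = 3.0
    alpha: float = 0.5
    ac: float = 1.0
    a_max: float = 2.0
    v_desired: float | None = None  # None = each driver's initial velocity
    belief_sigma_mode: str = "std"  # "std": sigma = .5 dt^2 sigma_a; "variance": sigma^2 = .5 dt^2 sigma_a^2
    risk_aggregation: str = "max"  # or "sum" (capped at 1)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0 or self.Tm <= 0 or self.fb <= 0:
            raise ValueError("dt, T, Tm, fb must be strictly positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        stride = 1.0 / (self.dt * self.fb)
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("1/(dt*fb) must be an integer number of steps")
        if self.belief_sigma_mode not in ("std", "variance"):
            raise ValueError("belief_sigma_mode must be 'std' or 'variance'")
        if self.risk_aggregation not in ("max", "sum"):
            raise ValueError("risk_aggregation must be 'max' or 'sum'")

    @property
    def belief_stride(self) -> int:
        """Simulation steps between consecutive belief points."""
        return round(1.0 / (self.dt * self.fb))

    @property
    def n_belief_points(self) -> int:
        return round(self.T * self.fb)

    @property
    def n_plan_steps(self) -> int:
        return round(self.T / self.dt)

    @property
    def memory_size(self) -> int:
        return round(self.Tm / self.dt)


def resistance(v: float) -> float:
    """Deceleration from rolling and aerodynamic resistance: 0.5 + 0.005 v^2."""
    if v < 0:
        raise ValueError("resistance undefined for negative velocity")
    return 0.5 + 0.005 * v * v


def step_vehicle(state: VehicleState, a_input: float, dt: float,
                 in_tunnel: bool = False) -> VehicleState:
    """Advance one timestep with semi-implicit Euler (update v, then s).

    Inside the tunnel the driver has no control authority and the velocity is
    held exactly constant (resistance is compensated); outside, the applied
    input fights resistance and the velocity is clamped at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if in_tunnel:
        return VehicleState(s=state.s + state.v * dt, v=state.v,
                            a_input=0.0, t=state.t + dt)
    v_new = state.v + (a_input - resistance(state.v)) * dt
    if v_new < 0.0:
        v_new = 0.0
    return VehicleState(s=state.s + v_new * dt, v=v_new,
                        a_input=a_input, t=state.t + dt)


#: headways paired with a nonzero relative velocity in the default design
_HEADWAYS_FULL = (-4.0, -2.0, 0.0, 2.0, 4.0)
_HEADWAYS_DV = (-4.0, 0.0, 4.0)


def default_condition_set() -> list[Condition]:
    """The default 11-condition design.

    Equal velocities are paired with all five projected headways; the
    +-0.8 m/s relative velocities only with headways {-4, 0, 4}. Every cell
    ends in a collision if both vehicles keep their initial velocity.
    """
    conds = [Condition(h, 0.0) for h in _HEADWAYS_FULL]
    for dv in (0.8, -0.8):
        conds.extend(Condition(h, dv) for h in _HEADWAYS_DV)
    return conds


def initial_states(condition: Condition, geometry: TrackGeometry,
                   v_base: float = 10.0) -> tuple[VehicleState, VehicleState]:
    """Initial (left, right) states realising a condition.

    Velocities are ``v_base +- dv/2``. The slower vehicle starts at s=0 and
    the faster one's start offset is solved such that, under constant
    velocities, the front-to-front distance at the instant the first front
    bumper reaches the merge point equals the projected headway. With equal
    velocities, the advantaged vehicle simply starts ahead by the headway.
    This placement is exactly mirror-symmetric.
    """
    dv = condition.relative_velocity
    h = condition.projected_headway
    vl = v_base + dv / 2.0
    vr = v_base - dv / 2.0
    if vl <= 0 or vr <= 0:
        raise ValueError("initial velocities must be positive")
    M = geometry.merge_point

    if vl == vr:
        sl, sr = (h, 0.0) if h >= 0 else (0.0, -h)
    else:
        left_fast = vl > vr
        v_f, v_s = (vl, vr) if left_fast else (vr, vl)
        # hf: required (fast - slow) front-to-front distance at first arrival
        hf = h if left_fast else -h
        t_slow = M / v_s
        candidates = []
        # slow vehicle arrives first (or tie): gap constraint at t_slow
        s0 = hf - (v_f - v_s) * t_slow
        if (M - s0) / v_f >= t_slow - 1e-12:
            candidates.append(s0)
        # fast vehicle arrives first: gap constraint at its own arrival
        s0 = (hf * v_f - (v_f - v_s) * M) / v_s
        if (M - s0) / v_f <= t_slow + 1e-12:
            candidates.append(s0)
        if not candidates:
            raise ValueError(f"no initial placement realises condition {condition.label}")
        s_fast = candidates[0]
        sl, sr = (s_fast, 0.0) if left_fast else (0.0, s_fast)

    return (VehicleState(s=sl, v=vl), VehicleState(s=sr, v=vr))


def detect_collision(s_left: float, s_right: float,
                     geometry: TrackGeometry) -> bool:
    """Shared-corridor collision rule.

    The roads only overlap within one vehicle length before the merge point;
    a collision requires both fronts past that boundary and a front-to-front
    distance smaller than the vehicle length.
    """
    L = geometry.vehicle_length
    boundary = geometry.merge_point - L
    return (min(s_left, s_right) > boundary
            and abs(s_left - s_right) < L)
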