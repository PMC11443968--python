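"""Behavioral measures on three levels: safety margins, outcomes, inputs.

* **merge gap** — the bumper-to-bumper clearance between the vehicles at the
  instant the trailing vehicle's front bumper crosses the merge point
  (crossing times are linearly interpolated between timesteps). Collision
  trials are excluded.
* **who merged first** — the side whose front bumper crossed the merge point
  earlier.
* **velocity deviations** — per-driver signed maximum/minimum and absolute
  maximum deviation from the initial velocity, from control onset onward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import TrialRecord
from .scenario import TrackGeometry

__all__ = [
    "CollisionTrialError",
    "TrialMetrics",
    "merge_gap",
    "who_first",
    "velocity_deviations",
    "trial_metrics",
    "batch_metrics",
    "batch_summary",
]


class CollisionTrialError(ValueError):
    """The requested measure excludes trials that ended in a collision."""


@dataclass(frozen=True)
class TrialMetrics:
    condition: str
    pair_id: int
    repetition: int
    collision: bool
    merge_gap: float  # nan for collision trials
    who_first: str
    max_dev_left: float
    min_dev_left: float
    max_abs_dev_left: float
    max_dev_right: float
    min_dev_right: float
    max_abs_dev_right: float


def _crossing_time(t: np.ndarray, s: np.ndarray, x: float) -> float:
    """First (interpolated) time the position trace reaches x."""
    idx = np.flatnonzero(s >= x)
    if idx.size == 0:
        raise ValueError("trace never reaches the requested position")
    i = int(idx[0])
    if i == 0 or s[i] == x:
        return float(t[i])
    frac = (x - s[i - 1]) / (s[i] - s[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _interp_position(t: np.ndarray, s: np.ndarray, when: float) -> float:
    return float(np.interp(when, t, s))


def merge_gap(record: TrialRecord, geometry: TrackGeometry) -> float:
    """Bumper-to-bumper clearance when the trailing vehicle crosses the merge
    point; raises :class:`CollisionTrialError` for collision trials."""
    if record.outcome.get("collision", False):
        raise CollisionTrialError("merge gap undefined for collision trials")
    M = geometry.merge_point
    t_cross = {side: _crossing_time(record.t, record.trace(side).s, M)
               for side in ("left", "right")}
    trailing = max(t_cross, key=t_cross.get)
    when = t_cross[trailing]
    s_l = _interp_position(record.t, record.left.s, when)
    s_r = _interp_position(record.t, record.right.s, when)
    return abs(s_l - s_r) - geometry.vehicle_length


def who_first(record: TrialRecord, geometry: TrackGeometry) -> str:
    """Side whose front bumper crossed the merge point first; exact ties are
    resolved by the position at trial end."""
    M = geometry.merge_point
    times = {}
    for side in ("left", "right"):
        try:
            times[side] = _crossing_time(record.t, record.trace(side).s, M)
        except ValueError:
            times[side] = math.inf
    if math.isinf(times["left"]) and math.isinf(times["right"]):
        raise ValueError("neither vehicle crossed the merge point")
    if times["left"] < times["right"]:
        return "left"
    if times["right"] < times["left"]:
        return "right"
    return "left" if record.left.s[-1] >= record.right.s[-1] else "right"


def velocity_deviations(record: TrialRecord, side: str
                        ) -> tuple[float, float, float]:
    """(max_dev, min_dev, max_abs_dev) of v - v_initial from control onset."""
    tr = record.trace(side)
    if tr.control_onset is None:
        return 0.0, 0.0, 0.0
    mask = record.t >= tr.control_onset
    dev = tr.v[mask] - tr.v_initial
    if dev.size == 0:
        return 0.0, 0.0, 0.0
    mx, mn = float(dev.max()), float(dev.min())
    return mx, mn, max(abs(mx), abs(mn))


def trial_metrics(record: TrialRecord, geometry: TrackGeometry) -> TrialMetrics:
    collision = bool(record.outcome.get("collision", False))
    gap = math.nan
    first = record.outcome.get("who_first", "none")
    if not collision:
        try:
            gap = merge_gap(record, geometry)
            first = who_first(record, geometry)
        except ValueError:
            pass  # stalled trial: a vehicle never reached the merge point
    devs = {side: velocity_deviations(record, side)
            for side in ("left", "right")}
    return TrialMetrics(
        condition=record.condition_label, pair_id=record.pair_id,
        repetition=record.repetition, collision=collision, merge_gap=gap,
        who_first=first,
        max_dev_left=devs["left"][0], min_dev_left=devs["left"][1],
        max_abs_dev_left=devs["left"][2],
        max_dev_right=devs["right"][0], min_dev_right=devs["right"][1],
        max_abs_dev_right=devs["right"][2])


def batch_metrics(records: list[TrialRecord],
                  geometry: TrackGeometry | None = None) -> pd.DataFrame:
    """One row of trial-level measures per record."""
    geometry = geometry or TrackGeometry()
    return pd.DataFrame([trial_metrics(r, geometry).__dict__
                         for r in records])


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI on a proportion (Wilson for small n)."""
    if n == 0:
        return math.nan, math.nan
    from statsmodels.stats.proportion import proportion_confint
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def batch_summary(records: list[TrialRecord], group_by: str = "condition",
                  geometry: TrackGeometry | None = None) -> pd.DataFrame:
    """Aggregate trial metrics per group.

    ``group_by`` is one of ``condition``, ``pair``, or ``driver`` (the latter
    summarising per-driver absolute deviations per pair and side). Collision
    trials are excluded from gap and deviation statistics and counted
    separately.
    """
    geometry = geometry or TrackGeometry()
    df = batch_metrics(records, geometry)
    if group_by == "pair":
        key = "pair_id"
    elif group_by == "condition":
        key = "condition"
    elif group_by == "driver":
        long = pd.concat([
            df.assign(side=side,
                      max_abs_dev=df[f"max_abs_dev_{side}"],
                      max_dev=df[f"max_dev_{side}"],
                      min_dev=df[f"min_dev_{side}"])
            for side in ("left", "right")], ignore_index=True)
        ok = long[~long.collision]
        g = ok.groupby(["pair_id", "side"])
        return pd.DataFrame({
            "n": g.size(),
            "mean_max_abs_dev": g["max_abs_dev"].mean(),
            "mean_max_dev": g["max_dev"].mean(),
            "mean_min_dev": g["min_dev"].mean(),
        }).reset_index()
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for name, grp in df.groupby(key):
        ok = grp[~grp.collision]
        n_ok = len(ok)
        if n_ok == 0:
            import warnings
            warnings.warn(f"group {name!r} has no non-collision trials; omitted")
            continue
        k_left = int((ok.who_first == "left").sum())
        ci = _binom_ci(k_left, n_ok)
        rows.append({
            key: name,
            "n": len(grp),
            "n_collisions": int(grp.collision.sum()),
            "mean_gap": float(ok.merge_gap.mean()),
            "gap_iqr_low": float(ok.merge_gap.quantile(0.25)),
            "gap_iqr_high": float(ok.merge_gap.quantile(0.75)),
            "mean_max_abs_dev": float(
                (ok.max_abs_dev_left + ok.max_abs_dev_right).mean() / 2),
            "p_left_first": k_left / n_ok,
            "p_left_first_ci_low": ci[0],
            "p_left_first_ci_high": ci[1],
        })
    return pd.DataFrame(rows)
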