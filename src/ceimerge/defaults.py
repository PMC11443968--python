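"""Fitted default parameters: per-driver base risk thresholds and the
population-level incentive coefficients.

The nine driver pairs below are the calibrated base thresholds (theta_l,
theta_u) per driver; the lambda coefficients are the shared incentive-function
slopes on (delta_p, delta_v, delta_p*delta_v), identical for all drivers.
"""

from __future__ import annotations

from .risk import RiskThresholds

__all__ = [
    "PAIR_THRESHOLDS",
    "LAMBDA_U",
    "LAMBDA_L",
    "default_pairs",
    "make_thresholds",
]

#: (theta_l, theta_u) per (pair, side); pairs are numbered 1..9
PAIR_THRESHOLDS: dict[tuple[int, str], tuple[float, float]] = {
    (1, "left"): (0.165, 0.495), (1, "right"): (0.260, 0.562),
    (2, "left"): (0.245, 0.635), (2, "right"): (0.058, 0.493),
    (3, "left"): (0.058, 0.488), (3, "right"): (0.245, 0.631),
    (4, "left"): (0.183, 0.537), (4, "right"): (0.201, 0.524),
    (5, "left"): (0.113, 0.498), (5, "right"): (0.269, 0.585),
    (6, "left"): (0.246, 0.550), (6, "right"): (0.161, 0.546),
    (7, "left"): (0.320, 0.736), (7, "right"): (0.201, 0.522),
    (8, "left"): (0.165, 0.525), (8, "right"): (0.246, 0.586),
    (9, "left"): (0.178, 0.519), (9, "right"): (0.227, 0.543),
}

#: incentive slopes (delta_p, delta_v, interaction) for the upper threshold
LAMBDA_U: tuple[float, float, float] = (0.003, 0.018, -0.006)
#: incentive slopes for the lower threshold
LAMBDA_L: tuple[float, float, float] = (0.004, 0.016, -0.003)


def make_thresholds(pair: int, side: str,
                    incentives: bool = True) -> RiskThresholds:
    """Calibrated thresholds for one driver; ``incentives=False`` gives the
    static-threshold variant (all lambdas zero)."""
    theta_l, theta_u = PAIR_THRESHOLDS[(pair, side)]
    if incentives:
        return RiskThresholds(theta_l, theta_u, LAMBDA_U, LAMBDA_L)
    return RiskThresholds(theta_l, theta_u)


def default_pairs(incentives: bool = True
                  ) -> list[tuple[RiskThresholds, RiskThresholds]]:
    """The nine calibrated driver pairs as (left, right) threshold tuples."""
    return [(make_thresholds(p, "left", incentives),
             make_thresholds(p, "right", incentives))
            for p in range(1, 10)]
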