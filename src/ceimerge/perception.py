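"""Noisy velocity perception and the kinematic belief about the other vehicle.

A driver observes the other vehicle's position and acceleration perfectly but
perceives its velocity through leaky evidence accumulation: the perceived
velocity moves a fraction ``alpha`` toward the true value each step and is
perturbed by Wiener noise of level ``beta``. From the perceived kinematics and
a short memory of observed accelerations, the driver projects a *belief*: a
set of future-time position distributions, each a two-component Gaussian
mixture — a core component for kinematically plausible motion and a
``phi``-times-wider component that reserves probability mass for unexpected
manoeuvres (e.g. emergency braking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .scenario import SimParams

__all__ = [
    "PerceptionState",
    "AccelerationMemory",
    "BeliefPoint",
    "Belief",
    "update_perceived_velocity",
    "expected_acceleration",
    "project_belief",
    "interval_probability",
    "mixture_interval_probability",
]


@dataclass
class PerceptionState:
    """What the ego driver currently perceives about the other vehicle."""

    v_perceived: float
    observed_position: float
    observed_acceleration: float = 0.0


class AccelerationMemory:
    """Ring buffer of the other vehicle's recent observed accelerations.

    Holds at most ``Tm/dt`` entries (the last Tm seconds); running first and
    second moments are maintained so mean/variance queries are O(1).
    """

    __slots__ = ("maxlen", "_buf", "_head", "_n", "_sum", "_sumsq")

    def __init__(self, maxlen: int):
        if maxlen < 1:
            raise ValueError("memory must hold at least one entry")
        self.maxlen = maxlen
        self._buf = [0.0] * maxlen
        self._head = 0
        self._n = 0
        self._sum = 0.0
        self._sumsq = 0.0

    def __len__(self) -> int:
        return self._n

    def append(self, a: float) -> None:
        if self._n == self.maxlen:
            old = self._buf[self._head]
            self._sum -= old
            self._sumsq -= old * old
        else:
            self._n += 1
        self._buf[self._head] = a
        self._sum += a
        self._sumsq += a * a
        self._head = (self._head + 1) % self.maxlen

    @property
    def mean(self) -> float:
        if self._n == 0:
            raise ValueError("acceleration memory is empty")
        return self._sum / self._n

    @property
    def variance(self) -> float:
        """Population variance of the buffer contents."""
        if self._n == 0:
            raise ValueError("acceleration memory is empty")
        m = self._sum / self._n
        var = self._sumsq / self._n - m * m
        return var if var > 0.0 else 0.0

    def contents(self) -> list[float]:
        """Time-ordered buffer contents, oldest first."""
        if self._n < self.maxlen:
            return self._buf[: self._n]
        return self._buf[self._head:] + self._buf[: self._head]


@dataclass(frozen=True)
class BeliefPoint:
    """Two-component Gaussian mixture over the other vehicle's position at a
    single future time: weights 1/2, means mu, std devs sigma and sigma*sqrt(phi)."""

    t: float
    mu: float
    sigma: float
    phi: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class Belief:
    """Belief points at frequency fb over the horizon T, as flat arrays.

    ``offsets[k]`` is the lead time of point k relative to the current
    instant (the current instant itself is excluded: it carries no
    planning-relevant collision information).
    """

    t0: float
    offsets: np.ndarray
    mus: np.ndarray
    sigmas: np.ndarray
    phi: float

    @property
    def points(self) -> list[BeliefPoint]:
        return [BeliefPoint(self.t0 + dt_k, mu, sig, self.phi)
                for dt_k, mu, sig in zip(self.offsets, self.mus, self.sigmas)]


def update_perceived_velocity(prev: float, v_real: float, alpha: float,
                              beta: float, dt: float,
                              rng: np.random.Generator | None = None) -> float:
    """One evidence-accumulation step of the perceived velocity.

    Returns ``prev + alpha (v_real - prev) + beta dW`` with
    ``dW ~ N(0, dt)`` (a Wiener increment over one step).
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    noise = 0.0
    if beta != 0.0:
        if rng is None:
            raise ValueError("rng required when beta != 0")
        noise = beta * rng.normal(0.0, math.sqrt(dt))
    return prev + alpha * (v_real - prev) + noise


def expected_acceleration(memory: AccelerationMemory,
                          ac: float) -> tuple[float, float]:
    """Mean and variance of the other vehicle's expected future acceleration.

    The mean is the memory average; the variance combines a comfortable
    acceleration band (99.7% of accelerations within +-ac, i.e. sd = ac/3)
    with the population variance of the recent observations, so inconsistent
    behaviour widens the belief.
    """
    if len(memory) == 0:
        raise ValueError("acceleration memory is empty; seed it with the first observation")
    base_sd = ac / 3.0
    return memory.mean, base_sd * base_sd + memory.variance


def project_belief(obs: PerceptionState, memory: AccelerationMemory,
                   params: SimParams, t0: float = 0.0) -> Belief:
    """Project the belief over the other vehicle's future positions.

    Constant-acceleration kinematics with the normally distributed expected
    acceleration: the position mean follows the deterministic rollout of the
    mean acceleration; the spread grows as ``0.5 (t-t0)^2 sigma_a``
    (exact Gaussian propagation of the acceleration uncertainty; set
    ``belief_sigma_mode="variance"`` to use the variance-based reading
    ``sigma_t^2 = 0.5 (t-t0)^2 sigma_a^2`` instead).
    """
    mu_a, var_a = expected_acceleration(memory, params.ac)
    n = params.n_belief_points
    offsets = np.arange(1, n + 1) / params.fb
    half_sq = 0.5 * offsets * offsets
    mus = half_sq * mu_a + offsets * obs.v_perceived + obs.observed_position
    if params.belief_sigma_mode == "std":
        sigmas = half_sq * math.sqrt(var_a)
    else:
        sigmas = np.sqrt(half_sq * var_a)
    return Belief(t0=t0, offsets=offsets, mus=mus, sigmas=sigmas,
                  phi=params.phi)


def mixture_interval_probability(mu, sigma, phi, lo, hi):
    """Vectorised P(lo <= X <= hi) for the two-component position mixture.

    Degenerate points (sigma == 0) resolve to an indicator of mu in [lo, hi].
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    mu, sigma, lo, hi = np.broadcast_arrays(mu, sigma, lo, hi)
    out = np.empty(mu.shape, dtype=float)
    degenerate = sigma == 0.0
    if degenerate.any():
        out[degenerate] = ((lo[degenerate] <= mu[degenerate])
                           & (mu[degenerate] <= hi[degenerate])).astype(float)
    ok = ~degenerate
    if ok.any():
        m, s = mu[ok], sigma[ok]
        s_wide = s * math.sqrt(phi)
        p = 0.5 * (ndtr((hi[ok] - m) / s) - ndtr((lo[ok] - m) / s))
        p += 0.5 * (ndtr((hi[ok] - m) / s_wide) - ndtr((lo[ok] - m) / s_wide))
        out[ok] = p
    return np.clip(out, 0.0, 1.0)


def interval_probability(point: BeliefPoint, lo: float, hi: float) -> float:
    """Probability that the other vehicle's position lies in [lo, hi]."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    return float(mixture_interval_probability(point.mu, point.sigma,
                                              point.phi, lo, hi))
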