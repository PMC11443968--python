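"""Per-trial logging containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DriverTrace", "TrialRecord"]


@dataclass
class DriverTrace:
    """Per-timestep log of one driver within a trial (arrays over rows)."""

    s: np.ndarray
    v: np.ndarray
    a_input: np.ndarray
    risk: np.ndarray
    rho_u: np.ndarray
    rho_l: np.ndarray
    event: list[str]
    v_initial: float
    control_onset: float | None  # time the front bumper passed the tunnel exit


@dataclass
class TrialRecord:
    """Full log of one dyadic merging trial.

    One row per timestep; ``outcome`` carries the trial-level summary
    (collision flag, interpolated merge order and gap, duration).
    """

    condition_label: str
    pair_id: int
    repetition: int
    seed: int
    dt: float
    t: np.ndarray
    left: DriverTrace
    right: DriverTrace
    outcome: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.t.size

    def trace(self, side: str) -> DriverTrace:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise ValueError(f"unknown side {side!r}")

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict = {
            "condition": self.condition_label,
            "pair": self.pair_id,
            "repetition": self.repetition,
            "seed": self.seed,
            "t": self.t,
        }
        for side in ("left", "right"):
            tr = self.trace(side)
            cols[f"s_{side}"] = tr.s
            cols[f"v_{side}"] = tr.v
            cols[f"a_input_{side}"] = tr.a_input
            cols[f"risk_{side}"] = tr.risk
            cols[f"rho_u_{side}"] = tr.rho_u
            cols[f"rho_l_{side}"] = tr.rho_l
            cols[f"event_{side}"] = tr.event
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
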