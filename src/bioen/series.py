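"""Uniform 0.5 Hz trial container shared by the simulator and preprocessing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialSeries", "GRID_DT"]

#: Node spacing of the model grid, s (0.5 Hz).
GRID_DT = 2.0


@dataclass
class TrialSeries:
    """Inputs (and optionally measured output) of one trial on the model grid.

    Attributes
    ----------
    t : ndarray
        Time in seconds, uniform with spacing :data:`GRID_DT`.
    u1 : ndarray
        Ergometer power output, W (piecewise constant per protocol segment).
    u2 : ndarray
        Expiratory minute ventilation, L·min⁻¹ BTPS.
    y : ndarray or None
        Measured aerobic metabolic rate MR_ae, W.
    segment_boundaries : list of float
        Times (s) at which the protocol switches power level; used for power
        smoothing and the day-to-day comparison metric.
    """

    t: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    y: np.ndarray | None = None
    segment_boundaries: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u1 = np.asarray(self.u1, dtype=float)
        self.u2 = np.asarray(self.u2, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("trial needs at least two nodes")
        dt = np.diff(self.t)
        if not np.allclose(dt, GRID_DT, rtol=0.0, atol=1e-9):
            raise ValueError(f"grid must be uniform at {GRID_DT} s spacing")
        for name in ("u1", "u2"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must match t in length")
        if self.y is not None and self.y.shape != (n,):
            raise ValueError("y must match t in length")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.t, "u1": self.u1, "u2": self.u2}
        if self.y is not None:
            cols["y"] = self.y
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, segment_boundaries: list[float] | None = None
    ) -> "TrialSeries":
        y = df["y"].to_numpy() if "y" in df.columns else None
        return cls(
            t=df["t"].to_numpy(),
            u1=df["u1"].to_numpy(),
            u2=df["u2"].to_numpy(),
            y=y,
            segment_boundaries=list(segment_boundaries or []),
        )
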