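"""Growth-curve post-processing: replicate statistics and two-point
early/late growth rates.

The early rate is the slope over the first reporting interval; the late
rate is the two-point slope over a post-breakthrough window.  Both
interval lengths depend on how deep the tumor was seeded (more stromal
layers delay breakthrough): early intervals of 10/20/50 days and late
windows of (30,60)/(120,200)/(400,600) days for 1/3/5 stromal layers.
For scaled-down domains the windows shrink by the domain-size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import GrowthTrajectory

__all__ = ["RateWindows", "average_replicates", "early_rate", "late_rate"]

#: layers -> (early interval, (late start, late end)) in days (full scale)
_DEFAULT_WINDOWS = {
    1: (10.0, (30.0, 60.0)),
    3: (20.0, (120.0, 200.0)),
    5: (50.0, (400.0, 600.0)),
}


@dataclass(frozen=True)
class RateWindows:
    layers: int
    early_interval_days: float
    late_window_days: tuple[float, float]

    @classmethod
    def for_layers(cls, layers: int, scale: float = 1.0) -> "RateWindows":
        """Windows for a layer count; ``scale`` < 1 shrinks them
        proportionally for scaled-down domains."""
        if layers not in _DEFAULT_WINDOWS:
            raise ValueError(f"no published window for {layers} stromal layers")
        early, (a, b) = _DEFAULT_WINDOWS[layers]
        rw = cls(layers, early * scale, (a * scale, b * scale))
        if rw.late_window_days[0] < rw.early_interval_days:
            raise ValueError("late window must start after the early interval")
        return rw


def average_replicates(trajectories: list[GrowthTrajectory]) -> pd.DataFrame:
    """Per-timepoint mean and sample SD of tumor counts across replicates."""
    if not trajectories:
        raise ValueError("no trajectories given")
    t0 = trajectories[0].times_days
    for tr in trajectories[1:]:
        if len(tr.times_days) != len(t0) or not np.allclose(tr.times_days, t0):
            raise ValueError("replicates must share a common time grid")
    counts = np.vstack([tr.tumor_count for tr in trajectories]).astype(float)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if len(trajectories) > 1 else np.zeros_like(mean)
    return pd.DataFrame({"t_days": t0, "mean": mean, "sd": sd})


def _value_at(curve: pd.DataFrame, t: float, tol: float = 1e-6) -> float:
    i = np.flatnonzero(np.isclose(curve["t_days"].to_numpy(), t, atol=tol))
    if i.size == 0:
        raise ValueError(f"curve has no timepoint at t = {t:g} days")
    return float(curve["mean"].to_numpy()[i[0]])


def early_rate(curve: pd.DataFrame, layers: int, scale: float = 1.0) -> float:
    """(N(t1) - N(0)) / t1 over the layer-specific early interval, cells/day."""
    w = RateWindows.for_layers(layers, scale)
    t1 = w.early_interval_days
    return (_value_at(curve, t1) - _value_at(curve, 0.0)) / t1


def late_rate(curve: pd.DataFrame, layers: int, scale: float = 1.0) -> float:
    """Two-point slope over the layer-specific late window, cells/day."""
    w = RateWindows.for_layers(layers, scale)
    a, b = w.late_window_days
    return (_value_at(curve, b) - _value_at(curve, a)) / (b - a)
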