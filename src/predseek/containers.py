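"""Shared data containers for paired daily/cumulative behavior index series.

A :class:`BehaviorSeries` holds one region's raw daily volumes for the two
health-information-seeking channels (online medical search, online medical
consultation).  A :class:`CumulativePair` holds the corresponding running
totals ``x1(t)``, ``x2(t)``, which are the state variables of the coupled
logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BehaviorSeries", "CumulativePair"]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class BehaviorSeries:
    """Daily search/consultation index values for one region.

    ``days`` are consecutive 1-based integer day indices; both daily series
    are nonnegative and of equal length (at least 3 days).
    """

    region_id: str
    days: np.ndarray
    search_daily: np.ndarray
    consult_daily: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.search_daily = _as_float_array(self.search_daily, "search_daily")
        self.consult_daily = _as_float_array(self.consult_daily, "consult_daily")
        n = len(self.days)
        if not (len(self.search_daily) == len(self.consult_daily) == n):
            raise ValueError("days, search_daily and consult_daily must have equal length")
        if n < 3:
            raise ValueError("a behavior series needs at least 3 days")
        if not np.array_equal(self.days, np.arange(self.days[0], self.days[0] + n)):
            raise ValueError("days must be consecutive integers")
        if np.any(self.search_daily < 0) or np.any(self.consult_daily < 0):
            raise ValueError("daily index values must be nonnegative")

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class CumulativePair:
    """Cumulative search/consultation trajectories ``x1(t)``, ``x2(t)``.

    Both trajectories are nonnegative and nondecreasing; ``x1[t]`` is the
    exact prefix sum of the daily search series through day ``days[t]``.
    """

    region_id: str
    days: np.ndarray
    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.x1 = _as_float_array(self.x1, "x1")
        self.x2 = _as_float_array(self.x2, "x2")
        if not (len(self.x1) == len(self.x2) == len(self.days)):
            raise ValueError("days, x1 and x2 must have equal length")

    def __len__(self) -> int:
        return len(self.days)
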