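"""Cumulative series construction and dynamic (growing-prefix) correlation.

The dynamic correlation trace of two aligned series is the absolute Pearson
correlation computed on growing prefixes ``[1..t]`` for ``t = 3..n`` — a
descriptive measure of how strongly the two behaviors co-move as the
observation window lengthens.  Traces from many regions are summarised by a
per-window mean and standard-deviation band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BehaviorSeries, CumulativePair

__all__ = [
    "CorrelationTrace",
    "cumulate",
    "to_daily",
    "dynamic_correlation",
    "correlation_summary",
]


@dataclass
class CorrelationTrace:
    """|Pearson r| over growing prefix windows for one region.

    ``value[i]`` is the absolute Pearson correlation of the two input
    prefixes ``[1..window_end[i]]``; windows with zero variance in either
    prefix carry NaN (undefined, never imputed).
    """

    region_id: str
    window_end: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.window_end = np.asarray(self.window_end, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.window_end) != len(self.value):
            raise ValueError("window_end and value must have equal length")
        defined = self.value[~np.isnan(self.value)]
        if np.any((defined < -1e-12) | (defined > 1 + 1e-12)):
            raise ValueError("defined correlation values must lie in [0, 1]")


def cumulate(series: BehaviorSeries) -> CumulativePair:
    """Exact prefix sums of the daily series (the model state variables)."""
    return CumulativePair(
        region_id=series.region_id,
        days=series.days.copy(),
        x1=np.cumsum(series.search_daily),
        x2=np.cumsum(series.consult_daily),
    )


def to_daily(pair: CumulativePair) -> BehaviorSeries:
    """Inverse of :func:`cumulate`: first differences with the day-1 level kept."""
    d1 = np.concatenate(([pair.x1[0]], np.diff(pair.x1)))
    d2 = np.concatenate(([pair.x2[0]], np.diff(pair.x2)))
    return BehaviorSeries(
        region_id=pair.region_id, days=pair.days.copy(), search_daily=d1, consult_daily=d2
    )


def dynamic_correlation(
    a, b, min_window: int = 3, region_id: str = ""
) -> CorrelationTrace:
    """Absolute Pearson correlation over growing prefixes ``[1..t]``.

    Starts at ``t = min_window`` (correlation needs at least three points)
    and adds one observation at a time up to the full series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be one-dimensional sequences of equal length")
    n = len(a)
    if n < min_window:
        raise ValueError(f"need at least min_window={min_window} observations, got {n}")
    ends = np.arange(min_window, n + 1)
    values = np.empty(len(ends))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, t in enumerate(ends):
            ap, bp = a[:t], b[:t]
            if np.ptp(ap) == 0 or np.ptp(bp) == 0:
                values[i] = np.nan
                continue
            values[i] = abs(np.corrcoef(ap, bp)[0, 1])
    return CorrelationTrace(region_id=region_id, window_end=ends, value=values)


def correlation_summary(traces: list[CorrelationTrace], ddof: int = 0) -> pd.DataFrame:
    """Per-window mean and sd band over an ensemble of correlation traces.

    Undefined (NaN) values are excluded; ``n`` counts the traces that
    contribute at each window end.  ``ddof=0`` gives the population sd
    (descriptive band); pass ``ddof=1`` for the sample convention.
    """
    if not traces:
        raise ValueError("need at least one trace")
    grid = traces[0].window_end
    for tr in traces[1:]:
        if not np.array_equal(tr.window_end, grid):
            raise ValueError("traces must share the same window grid")
    mat = np.vstack([tr.value for tr in traces])
    n = np.sum(~np.isnan(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=ddof)
    sd = np.where(n > ddof, sd, np.nan)
    return pd.DataFrame({"window_end": grid, "mean": mean, "sd": sd, "n": n})
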