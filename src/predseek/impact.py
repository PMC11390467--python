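"""Impact-function series φ1(t), φ2(t) and sign-regime classification.

Every structural factor of the search equation carries the partner variable
x2, and every factor of the consultation equation carries x1, so each
equation's interaction term factors as ``f1 = x2 · φ1`` and ``f2 = x1 · φ2``.
The per-day magnitudes φ1(t) and φ2(t) gauge, respectively, the impact of
consultation on search and of search on consultation.  A predominantly
negative φ1 with predominantly positive φ2 is the predator–prey signature:
consultation inhibits search while search promotes consultation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CumulativePair
from .dynamics import CONSULT_FACTORS, SEARCH_FACTORS

__all__ = ["ImpactSeries", "compute_impact", "classify_regime", "impact_matrix"]

# factor / partner-variable, per equation, in canonical factor order
_PHI_SEARCH = {  # f / x2
    "x2": lambda x1, x2: np.ones_like(x1),
    "x2^2": lambda x1, x2: x2,
    "x1*x2": lambda x1, x2: x1,
    "x1*x2^2": lambda x1, x2: x1 * x2,
    "x1^2*x2": lambda x1, x2: x1 * x1,
    "x1^2*x2^2": lambda x1, x2: x1 * x1 * x2,
}
_PHI_CONSULT = {  # f / x1
    "x1": lambda x1, x2: np.ones_like(x1),
    "x1^2": lambda x1, x2: x1,
    "x1*x2": lambda x1, x2: x2,
    "x1^2*x2": lambda x1, x2: x1 * x2,
    "x1*x2^2": lambda x1, x2: x2 * x2,
    "x1^2*x2^2": lambda x1, x2: x1 * x2 * x2,
}


@dataclass
class ImpactSeries:
    """φ1 and φ2 evaluated on a day range for one region."""

    region_id: str
    days: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.phi1 = np.asarray(self.phi1, dtype=float)
        self.phi2 = np.asarray(self.phi2, dtype=float)
        if not (len(self.phi1) == len(self.phi2) == len(self.days)):
            raise ValueError("days, phi1 and phi2 must have equal length")
        if not (np.all(np.isfinite(self.phi1)) and np.all(np.isfinite(self.phi2))):
            raise ValueError("impact values must be finite")


def compute_impact(
    coeffs_search,
    coeffs_consult,
    pair: CumulativePair,
    day_range: tuple[int, int] | None = None,
) -> ImpactSeries:
    """Evaluate φ1(t), φ2(t) from fitted coefficient vectors on a trajectory.

    ``coeffs_search`` / ``coeffs_consult`` are full length-6 vectors over the
    canonical factor orders (absent factors zero).  ``day_range`` is an
    inclusive day interval; default is the whole series.  Because every
    factor of each equation contains its partner variable, the factorisation
    ``f = partner · φ`` always exists here.
    """
    a = np.asarray(coeffs_search, dtype=float)
    b = np.asarray(coeffs_consult, dtype=float)
    if a.shape != (6,) or b.shape != (6,):
        raise ValueError("coefficient vectors must have length 6")
    if day_range is None:
        day_range = (int(pair.days[0]), int(pair.days[-1]))
    lo, hi = day_range
    if lo < pair.days[0] or hi > pair.days[-1] or lo > hi:
        raise ValueError(f"day_range {day_range} outside available days "
                         f"[{pair.days[0]}, {pair.days[-1]}]")
    mask = (pair.days >= lo) & (pair.days <= hi)
    x1, x2 = pair.x1[mask], pair.x2[mask]
    phi1 = sum(a[i] * _PHI_SEARCH[f](x1, x2) for i, f in enumerate(SEARCH_FACTORS))
    phi2 = sum(b[i] * _PHI_CONSULT[f](x1, x2) for i, f in enumerate(CONSULT_FACTORS))
    return ImpactSeries(
        region_id=pair.region_id,
        days=pair.days[mask],
        phi1=np.broadcast_to(phi1, x1.shape).astype(float),
        phi2=np.broadcast_to(phi2, x1.shape).astype(float),
    )


def classify_regime(series: ImpactSeries, tail_fraction: float = 0.5) -> dict[str, str]:
    """Label each channel by the majority sign over the trailing days.

    The trailing window holds ``ceil(tail_fraction · n)`` days; exact zeros
    count toward neither sign.  Labels: ``predominantly-positive``,
    ``predominantly-negative`` or ``mixed``.
    """
    if not (0 < tail_fraction <= 1):
        raise ValueError("tail_fraction must lie in (0, 1]")
    n = len(series.days)
    tail = int(np.ceil(tail_fraction * n))

    def label(values: np.ndarray) -> str:
        v = values[-tail:]
        pos = int(np.sum(v > 0))
        neg = int(np.sum(v < 0))
        if pos > neg:
            return "predominantly-positive"
        if neg > pos:
            return "predominantly-negative"
        return "mixed"

    return {"phi1": label(series.phi1), "phi2": label(series.phi2)}


def impact_matrix(results: list[ImpactSeries], channel: str = "phi1") -> pd.DataFrame:
    """Region × day matrix of one impact channel (heatmap-ready).

    Rows follow the input order; columns are the union of day grids, with
    NaN where a region has no value.
    """
    if channel not in ("phi1", "phi2"):
        raise ValueError("channel must be 'phi1' or 'phi2'")
    if not results:
        raise ValueError("need at least one impact series")
    all_days = sorted({int(d) for s in results for d in s.days})
    mat = pd.DataFrame(
        np.nan, index=[s.region_id for s in results], columns=all_days, dtype=float
    )
    for s in results:
        mat.loc[s.region_id, list(map(int, s.days))] = getattr(s, channel)
    mat.index.name = "region"
    return mat
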