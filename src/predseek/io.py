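"""CSV/JSON readers and writers for ensembles, traces and result tables.

All numeric output uses 17 significant digits so that write/read round-trips
are exact, and all writers are deterministic (sorted keys, fixed line
endings) so that repeated runs with the same seed produce identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BehaviorSeries
from .correlation import CorrelationTrace
from .structures import ConformityResult

__all__ = [
    "FLOAT_FMT",
    "write_ensemble",
    "read_ensemble",
    "write_traces",
    "write_summary",
    "write_ranking",
    "write_matrix",
    "read_matrix",
    "write_json",
]

FLOAT_FMT = "%.17g"


def _write_df(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT, lineterminator="\n")


def write_ensemble(ensemble: list[BehaviorSeries], path) -> None:
    """Long-format CSV: ``region,day,search_daily,consult_daily``."""
    frames = [
        pd.DataFrame(
            {
                "region": s.region_id,
                "day": s.days,
                "search_daily": s.search_daily,
                "consult_daily": s.consult_daily,
            }
        )
        for s in ensemble
    ]
    _write_df(pd.concat(frames, ignore_index=True), path)


def read_ensemble(path) -> list[BehaviorSeries]:
    """Read the long-format ensemble CSV back into per-region series."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"region", "day", "search_daily", "consult_daily"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ensemble CSV is missing columns: {sorted(missing)}")
    bad = df[df[["search_daily", "consult_daily"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"malformed ensemble CSV row at line {int(bad.index[0]) + 2}")
    out = []
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("day")
        out.append(
            BehaviorSeries(
                region_id=str(region),
                days=grp["day"].to_numpy(),
                search_daily=grp["search_daily"].to_numpy(),
                consult_daily=grp["consult_daily"].to_numpy(),
            )
        )
    return out


def write_traces(traces: list[CorrelationTrace], path) -> None:
    """Long-format CSV: ``region,window_end,value``."""
    frames = [
        pd.DataFrame({"region": t.region_id, "window_end": t.window_end, "value": t.value})
        for t in traces
    ]
    _write_df(pd.concat(frames, ignore_index=True), path)


def write_summary(summary: pd.DataFrame, path) -> None:
    """CSV: ``window_end,mean,sd,n``."""
    _write_df(summary, path)


def write_ranking(ranked: list[ConformityResult], equation: str, path) -> None:
    """CSV: ``equation,structure_id,n_factors,signs,np,ntotal,cr,mean_r2,rank``."""
    rows = [
        {
            "equation": equation,
            "structure_id": res.structure.id,
            "n_factors": len(res.structure.factors),
            "signs": "".join("+" if s > 0 else "-" for s in res.structure.signs),
            "np": res.n_pass,
            "ntotal": res.n_total,
            "cr": res.cr,
            "mean_r2": res.mean_r2,
            "rank": rank,
        }
        for rank, res in enumerate(ranked, start=1)
    ]
    _write_df(pd.DataFrame(rows), path)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Region × day matrix CSV (rows = regions, columns = days)."""
    _write_df(matrix, path, index=True)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.columns = df.columns.astype(int)
    return df


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
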