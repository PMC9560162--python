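"""Tidy CSV / JSON readers and writers for every pipeline stage."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circstats import StroboscopicMap
from .signal import PhaseSeries, Timeseries

TIMESERIES_COLUMNS = ("sample_id", "time_min", "intensity")

__all__ = [
    "load_timeseries_csv",
    "write_timeseries_csv",
    "write_phase_csv",
    "write_strobo_csv",
    "load_strobo_csv",
    "write_json",
    "write_tongue_csv",
    "write_contours_csv",
]


class FormatError(ValueError):
    """Malformed tabular input (missing columns, bad cells, bad sampling)."""


def load_timeseries_csv(path, value_col: str | None = None) -> list[Timeseries]:
    """Read a tidy ``sample_id,time_min,<value>`` CSV into Timeseries.

    The value column is ``intensity`` by default; a ``detrended`` column is
    accepted as a fallback so per-stage outputs chain without renaming.
    Rows may arrive in any order; each sample is sorted by time and its
    sampling validated (uniform grid, >= 16 points).  Errors name the
    offending sample or row.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if value_col is None:
        value_col = ("detrended" if "detrended" in df.columns
                     and "intensity" not in df.columns else "intensity")
    missing = [c for c in ("sample_id", "time_min", value_col)
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.rename(columns={value_col: "intensity"})
    for col in ("time_min", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric {col!r} at row {bad[0] + 2} "
                f"(value {df[col][bad[0]]!r})"
            )
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise FormatError(f"{path}: empty {col!r} at row {row + 2}")
        df[col] = vals
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("time_min")
        try:
            out.append(Timeseries(
                sample_id=str(sid),
                t=grp["time_min"].to_numpy(),
                y=grp["intensity"].to_numpy(),
            ))
        except ValueError as e:
            raise FormatError(f"{path}: sample {sid!r}: {e}") from e
    return out


def write_timeseries_csv(series: list, path, value_col: str = "intensity"):
    frames = [
        pd.DataFrame({"sample_id": ts.sample_id, "time_min": ts.t,
                      value_col: ts.y})
        for ts in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_phase_csv(series: list[PhaseSeries], path):
    frames = [
        pd.DataFrame({
            "sample_id": ps.sample_id, "time_min": ps.t,
            "period_min": ps.period, "power": ps.power,
            "phase_rad": ps.phi, "masked": ps.mask.astype(int),
        })
        for ps in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_strobo_csv(maps: list[StroboscopicMap], path):
    frames = [
        pd.DataFrame({
            "sample_id": m.sample_id,
            "pulse_index": m.pulse_indices,
            "phi_old_rad": m.phi_old,
            "phi_new_rad": m.phi_new,
        })
        for m in maps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_strobo_csv(path) -> list[StroboscopicMap]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    need = ("sample_id", "pulse_index", "phi_old_rad", "phi_new_rad")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("pulse_index")
        out.append(StroboscopicMap(
            sample_id=str(sid),
            pairs=grp[["phi_old_rad", "phi_new_rad"]].to_numpy(),
            pulse_indices=grp["pulse_index"].to_numpy(dtype=int),
        ))
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path):
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))


def write_tongue_csv(grid, path):
    """Long-format ``T_zeit,eps,locked,n,m,rho,phi_ent`` export of a TongueGrid."""
    rows = []
    for i, e in enumerate(grid.eps_grid):
        for j, tz in enumerate(grid.T_zeit_grid):
            rows.append({
                "T_zeit": tz, "eps": e, "locked": int(grid.locked[i, j]),
                "n": grid.ratio_n[i, j], "m": grid.ratio_m[i, j],
                "rho": grid.rho[i, j], "phi_ent": grid.phi_ent[i, j],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_contours_csv(contours: dict, path):
    rows = []
    for level, lines in contours.items():
        for li, line in enumerate(lines):
            for T, e in line:
                rows.append({"level_rad": level, "polyline": li,
                             "T_zeit": T, "eps": e})
    pd.DataFrame(rows, columns=["level_rad", "polyline", "T_zeit", "eps"]).to_csv(
        path, index=False)
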