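"""CSV readers/writers for head series, trajectories and budgets.

All writers are deterministic; floats use 17 significant digits so a
write/read round-trip is lossless.  Times export as ISO-8601 when the
series carries a calendar anchor, plus an hours-since-start column that
is authoritative for parsing.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .budget import NitrateBudget
from .hydrology import HeadSeries
from .transport import SPECIES, SimTrajectory

__all__ = ["write_head_series", "read_head_series", "write_budget",
           "write_trajectory", "write_velocity_series"]

_FLOAT_FMT = "%.17g"


class HeadSeriesParseError(ValueError):
    pass


def write_head_series(series: HeadSeries, path: str | Path) -> None:
    cols = {"time_h": series.times_h}
    if series.season_start is not None:
        t0 = datetime.combine(series.season_start, datetime.min.time())
        cols["time_iso"] = [
            (t0 + timedelta(hours=float(h))).isoformat() for h in series.times_h]
    cols["h_up_m"] = series.h_up
    cols["h_dn_m"] = series.h_dn
    df = pd.DataFrame(cols)
    df.attrs["separation_m"] = series.separation_m
    with open(path, "w") as fh:
        fh.write(f"# separation_m={series.separation_m!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_head_series(path: str | Path, allow_gaps: bool = True) -> HeadSeries:
    """Parse a head-series CSV; errors name the offending row.

    A gap in the hourly cadence is accepted with a warning (no
    interpolation is performed unless the caller resamples explicitly).
    """
    sep = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# separation_m="):
            sep = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("time_h", "h_up_m", "h_dn_m"):
        if col not in df.columns:
            raise HeadSeriesParseError(f"missing column {col!r}")
    t = df["time_h"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise HeadSeriesParseError(
            f"non-monotone time at row {int(bad[0]) + 1}")
    gaps = np.nonzero(np.diff(t) > 1.0 + 1e-9)[0]
    if gaps.size:
        import warnings
        warnings.warn(f"head series has {gaps.size} gap(s) in hourly cadence; "
                      "not interpolated", stacklevel=2)
        if not allow_gaps:
            raise HeadSeriesParseError(f"cadence gap at row {int(gaps[0]) + 1}")
    start = None
    if "time_iso" in df.columns:
        start = datetime.fromisoformat(str(df["time_iso"].iloc[0])).date()
    return HeadSeries(t, df["h_up_m"].to_numpy(dtype=float),
                      df["h_dn_m"].to_numpy(dtype=float),
                      separation_m=sep if sep is not None else 58.0,
                      season_start=start)


def write_budget(budget: NitrateBudget, path: str | Path) -> None:
    pd.DataFrame({
        "time_d": budget.times_d,
        "influx_mol_m2_d": budget.influx,
        "outflux_mol_m2_d": budget.outflux,
        "removal_mol_m2_d": budget.removal,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_velocity_series(traj: SimTrajectory, path: str | Path) -> None:
    pd.DataFrame({
        "time_h": traj.times_h,
        "gradient_m_m": traj.gradient,
        "darcy_flux_m_s": traj.velocity * traj.model.geometry.porosity,
        "pore_velocity_m_s": traj.velocity,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trajectory(traj: SimTrajectory, path: str | Path) -> None:
    """Tidy long-format snapshots: time, cell, x, species, mol/L."""
    geom = traj.model.geometry
    frames = []
    x = geom.x_centers
    for t, snap in zip(traj.snap_times_h, traj.snapshots):
        for si, sp in enumerate(SPECIES):
            frames.append(pd.DataFrame({
                "time_h": t, "cell_index": np.arange(geom.n_cells),
                "x_m": x, "species": sp, "conc_mol_L": snap[si]}))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
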