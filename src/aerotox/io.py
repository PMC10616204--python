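"""CSV interchange formats.

PNSD CSV (wide): first column ``timestamp`` (ISO-8601 local time),
remaining headers are bin mid-diameters in nm, cells are dN/dlog10(d_p)
in cm^-3.  Daily table CSV: one row per 08:00-anchored day.  Dialect:
comma-separated, UTF-8, '.' decimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import SizeGrid

__all__ = ["read_pnsd_csv", "write_pnsd_csv", "read_daily_csv", "write_daily_csv"]


def read_pnsd_csv(path) -> tuple[pd.DataFrame, SizeGrid]:
    """Read a wide PNSD CSV; returns (frame, grid inferred from headers)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df.columns[0] != "timestamp":
        raise ValueError(f"{path}: first column must be 'timestamp', got {df.columns[0]!r}")
    try:
        diameters = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric diameter header: {exc}") from None
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    dup = ts[ts.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate timestamps: {list(dup.astype(str)[:5])}")
    if not ts.is_monotonic_increasing:
        bad = ts[ts.diff() < pd.Timedelta(0)]
        raise ValueError(f"{path}: non-monotone timestamps at {list(bad.astype(str)[:5])}")
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    nan_rows = values.isna().any(axis=1)
    if nan_rows.any():
        lines = list(np.nonzero(nan_rows.to_numpy())[0][:5] + 2)  # 1-based + header
        raise ValueError(f"{path}: malformed/missing values on lines {lines}")
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative concentrations")
    out = values.copy()
    out.index = pd.DatetimeIndex(ts, name="timestamp")
    return out, SizeGrid.from_midpoints(diameters)


def write_pnsd_csv(pnsd: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    pnsd.to_csv(path, index_label="timestamp", float_format=float_format)


def write_daily_csv(table: pd.DataFrame, path, float_format: str = "%.8g") -> None:
    table.to_csv(path, index_label="window_start", float_format=float_format)


def read_daily_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="window_start", parse_dates=["window_start"])
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df
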