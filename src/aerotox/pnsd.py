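"""Integrals over particle number size distributions and time aggregation.

A PNSD time series is a pandas DataFrame with a DatetimeIndex (strictly
increasing local wall-clock timestamps) and one float column per grid
bin, holding dN/dlog10(d_p) in cm^-3.  All integrals are midpoint sums
consistent with :class:`aerotox.grids.SizeGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DensityModel, SizeGrid

__all__ = [
    "integrate_number",
    "pm_mass_from_pnsd",
    "ebc_from_absorption",
    "daily_aggregate",
    "DailyAggregate",
]

#: default mass absorption cross-section for equivalent black carbon at 880 nm
MAC_880_M2_PER_G = 7.77


def _check_conc(dndlogdp, grid: SizeGrid) -> np.ndarray:
    y = np.asarray(dndlogdp, dtype=float)
    if y.shape[-1] != grid.n_bins:
        raise ValueError("dndlogdp length must match grid")
    if np.any(y < 0):
        raise ValueError("concentrations must be non-negative")
    return y


def integrate_number(dndlogdp, grid: SizeGrid, d_low: float | None = None,
                     d_high: float | None = None) -> float | np.ndarray:
    """Number concentration (cm^-3) in the diameter band [d_low, d_high) nm.

    Defaults to the full grid range (N_t).  Accepts a single record or a
    2-d array (records x bins), returning a scalar or per-record vector.
    """
    y = _check_conc(dndlogdp, grid)
    if d_low is None and d_high is None:
        mask = np.ones(grid.n_bins, dtype=bool)
    else:
        d_low = grid.d_min if d_low is None else d_low
        d_high = grid.d_max if d_high is None else d_high
        mask = grid.band_mask(d_low, d_high)
    out = (y[..., mask] * grid.dlog[mask]).sum(axis=-1)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def pm_mass_from_pnsd(dndlogdp, grid: SizeGrid, density: DensityModel | None = None,
                      d_max: float = 1000.0) -> float | np.ndarray:
    """Particle mass concentration (ug m^-3) assuming spherical particles.

    Sums (pi/6) d_p^3 rho(d_p) dN over bins with midpoint below ``d_max``
    nm; the default density model rises from 1.25 to 1.5 g cm^-3 across
    the 8-1000 nm range.
    """
    y = _check_conc(dndlogdp, grid)
    density = density or DensityModel()
    d = grid.mid_diameters_nm
    mask = d < d_max
    d_m = d[mask] * 1e-9
    rho_kg_m3 = density.rho(d[mask]) * 1000.0
    # per-particle mass [kg] x number per bin [m^-3] -> kg/m^3 -> ug/m^3
    per_particle = (np.pi / 6.0) * d_m**3 * rho_kg_m3
    n_per_bin_m3 = y[..., mask] * grid.dlog[mask] * 1e6
    out = (per_particle * n_per_bin_m3).sum(axis=-1) * 1e9
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def ebc_from_absorption(b_abs_880_Mm: float | np.ndarray,
                        mac_m2_per_g: float = MAC_880_M2_PER_G):
    """Equivalent black carbon mass (ug m^-3) from 880 nm absorption (Mm^-1).

    eBC = b_abs / MAC; with the aethalometer default MAC of 7.77 m^2 g^-1,
    7.77 Mm^-1 maps to exactly 1 ug m^-3.
    """
    b = np.asarray(b_abs_880_Mm, dtype=float)
    if np.any(b < 0):
        raise ValueError("absorption coefficient must be non-negative")
    if mac_m2_per_g <= 0:
        raise ValueError("MAC must be positive")
    out = b / mac_m2_per_g
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DailyAggregate:
    """08:00-anchored daily means with per-window coverage."""

    values: pd.DataFrame  # one row per window, columns = input columns
    coverage: pd.Series  # fraction of the expected records present
    flagged: pd.Series  # True where coverage < min_coverage

    def unflagged(self) -> pd.DataFrame:
        return self.values.loc[~self.flagged]


def daily_aggregate(series: pd.Series | pd.DataFrame, window_start_hour: int = 8,
                    min_coverage: float = 0.75) -> DailyAggregate:
    """Aggregate a timestamped series into 08:00->08:00 daily means.

    Each window is labelled by the date on which it starts.  Coverage is
    the number of records present divided by the number expected at the
    series' median cadence; windows below ``min_coverage`` are flagged
    (their means are still computed from the available records).
    """
    if isinstance(series, pd.Series):
        frame = series.to_frame()
    else:
        frame = series
    if frame.empty:
        raise ValueError("cannot aggregate an empty series")
    if not isinstance(frame.index, pd.DatetimeIndex):
        raise TypeError("index must be a DatetimeIndex")
    if not frame.index.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted")

    anchor = pd.Timedelta(hours=window_start_hour)
    window_key = (frame.index - anchor).floor("1D") + anchor
    values = frame.groupby(window_key).mean()
    counts = frame.groupby(window_key).size()

    if len(frame) > 1:
        cadence = frame.index.to_series().diff().dropna().median()
        expected = max(int(round(pd.Timedelta(days=1) / cadence)), 1)
    else:
        expected = 1
    coverage = (counts / expected).clip(upper=1.0)
    coverage.name = "coverage"
    flagged = coverage < min_coverage
    flagged.name = "flagged"
    values.index.name = "window_start"
    return DailyAggregate(values=values, coverage=coverage, flagged=flagged)
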