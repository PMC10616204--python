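"""Diameter grids and the size-dependent particle density model.

Particle number size distributions (PNSDs) are stored as dN/dlog10(d_p)
values on a fixed grid of geometric bin mid-diameters, the convention of
SMPS exports.  Integrals over the distribution are midpoint sums
``sum(dndlogdp * dlog10)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SizeGrid", "make_size_grid", "DensityModel"]


@dataclass(frozen=True)
class SizeGrid:
    """A fixed grid of aerosol diameter bins.

    Parameters
    ----------
    mid_diameters_nm : ndarray
        Geometric bin mid-diameters in nm, strictly increasing, all > 0.
    dlog : ndarray
        Bin widths in log10(d_p) units, one per bin, all > 0.
    """

    mid_diameters_nm: np.ndarray
    dlog: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.mid_diameters_nm, dtype=float)
        w = np.asarray(self.dlog, dtype=float)
        if d.ndim != 1 or w.shape != d.shape:
            raise ValueError("mid_diameters_nm and dlog must be 1-d arrays of equal length")
        if d.size == 0:
            raise ValueError("grid must have at least one bin")
        if np.any(d <= 0):
            raise ValueError("all diameters must be positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(w <= 0):
            raise ValueError("all log-widths must be positive")
        object.__setattr__(self, "mid_diameters_nm", d)
        object.__setattr__(self, "dlog", w)

    @property
    def n_bins(self) -> int:
        return self.mid_diameters_nm.size

    @property
    def d_min(self) -> float:
        """Lower edge of the first bin (nm)."""
        return float(self.mid_diameters_nm[0] * 10 ** (-self.dlog[0] / 2))

    @property
    def d_max(self) -> float:
        """Upper edge of the last bin (nm)."""
        return float(self.mid_diameters_nm[-1] * 10 ** (self.dlog[-1] / 2))

    @classmethod
    def from_midpoints(cls, mid_diameters_nm) -> "SizeGrid":
        """Reconstruct a grid from midpoints alone (e.g. CSV headers).

        Log-widths are the central log10 spacing of the midpoints, with
        one-sided differences at the ends.
        """
        d = np.asarray(mid_diameters_nm, dtype=float)
        if d.size < 2:
            raise ValueError("need at least two midpoints to infer bin widths")
        logd = np.log10(d)
        w = np.empty_like(logd)
        w[1:-1] = (logd[2:] - logd[:-2]) / 2.0
        w[0] = logd[1] - logd[0]
        w[-1] = logd[-1] - logd[-2]
        return cls(d, w)

    def band_mask(self, d_low: float, d_high: float) -> np.ndarray:
        """Boolean mask of bins with midpoint in [d_low, d_high) nm."""
        if not d_low < d_high:
            raise ValueError(f"need d_low < d_high, got [{d_low}, {d_high})")
        d = self.mid_diameters_nm
        if d_high <= d[0] or d_low > d[-1]:
            raise ValueError(
                f"band [{d_low}, {d_high}) nm lies outside grid coverage "
                f"[{d[0]:.3g}, {d[-1]:.3g}] nm"
            )
        return (d >= d_low) & (d < d_high)


def make_size_grid(d_min: float, d_max: float, bins_per_decade: int = 16) -> SizeGrid:
    """Build a geometrically spaced grid covering [d_min, d_max] nm.

    Bin edges start at ``d_min`` with uniform width ``1/bins_per_decade``
    in log10(d_p); the number of bins is the smallest count whose upper
    edge reaches ``d_max``.  Midpoints are geometric means of the edges.

    >>> make_size_grid(8, 1000, 16).n_bins
    34
    """
    if not (0 < d_min < d_max):
        raise ValueError(f"need 0 < d_min < d_max, got ({d_min}, {d_max})")
    if bins_per_decade < 4:
        raise ValueError("bins_per_decade must be >= 4")
    n = math.ceil(bins_per_decade * math.log10(d_max / d_min))
    step = 1.0 / bins_per_decade
    log_edges = math.log10(d_min) + step * np.arange(n + 1)
    mids = 10 ** ((log_edges[:-1] + log_edges[1:]) / 2.0)
    return SizeGrid(mids, np.full(n, step))


@dataclass(frozen=True)
class DensityModel:
    """Size-dependent particle density, linear in log10(d_p).

    Density rises from ``rho_min`` at ``d_low_nm`` to ``rho_max`` at
    ``d_high_nm`` (defaults 1.25 g/cm^3 at 8 nm to 1.5 g/cm^3 at 1000 nm),
    clamped outside that range.  A constant density is the degenerate case
    ``rho_min == rho_max``.
    """

    rho_min: float = 1.25
    rho_max: float = 1.5
    d_low_nm: float = 8.0
    d_high_nm: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.rho_min <= self.rho_max):
            raise ValueError("need 0 < rho_min <= rho_max")
        if not (0 < self.d_low_nm < self.d_high_nm):
            raise ValueError("need 0 < d_low_nm < d_high_nm")

    def rho(self, d_nm) -> np.ndarray:
        """Density in g/cm^3 at diameter(s) d_nm."""
        d = np.asarray(d_nm, dtype=float)
        frac = (np.log10(d) - np.log10(self.d_low_nm)) / (
            np.log10(self.d_high_nm) - np.log10(self.d_low_nm)
        )
        frac = np.clip(frac, 0.0, 1.0)
        return self.rho_min + frac * (self.rho_max - self.rho_min)

    @classmethod
    def constant(cls, rho: float) -> "DensityModel":
        return cls(rho_min=rho, rho_max=rho)
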