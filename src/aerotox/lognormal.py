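"""Multi-lognormal representation of particle number size distributions.

An aerosol mode is the triplet (N, gmd, gsd): number concentration in
cm^-3, geometric mean diameter in nm, geometric standard deviation
(dimensionless, > 1).  In dN/dlog10(d_p) space a mode is a Gaussian in
log10(d_p):

    dN/dlog10(d_p) = N / (sqrt(2*pi) * log10(gsd))
                     * exp(-(log10 d_p - log10 gmd)^2 / (2 log10^2 gsd))

so that the integral over log10(d_p) of one mode is exactly N.

`MultiLognormalModel` fits 1..max_modes such modes to a measured
distribution by bounded least squares in log-concentration space, with
the mode count selected by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .grids import SizeGrid

__all__ = ["LognormalMode", "evaluate_modes", "MultiLognormalModel", "MultiLognormalResults"]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class LognormalMode:
    """One lognormal aerosol mode: (N, gmd, gsd)."""

    number: float  # cm^-3
    gmd: float  # nm
    gsd: float  # dimensionless, > 1

    def __post_init__(self) -> None:
        if self.number < 0:
            raise ValueError("mode number concentration must be >= 0")
        if self.gmd <= 0:
            raise ValueError("geometric mean diameter must be > 0")
        if self.gsd <= 1:
            raise ValueError("geometric standard deviation must be > 1")


def evaluate_modes(modes, grid: SizeGrid) -> np.ndarray:
    """Evaluate the summed dN/dlog10(d_p) of `modes` on `grid` (cm^-3)."""
    out = np.zeros(grid.n_bins)
    logd = np.log10(grid.mid_diameters_nm)
    for m in modes:
        if m.gsd <= 1:
            raise ValueError("geometric standard deviation must be > 1")
        s = np.log10(m.gsd)
        out += m.number / (_SQRT2PI * s) * np.exp(-((logd - np.log10(m.gmd)) ** 2) / (2 * s * s))
    return out


def _pack(modes_arr: np.ndarray) -> np.ndarray:
    # parameter vector is log10 of (N, gmd, log10 gsd) per mode, for scale-free optimization
    return np.log10(modes_arr).ravel()


def _unpack(theta: np.ndarray) -> np.ndarray:
    return 10.0 ** theta.reshape(-1, 3)


def _model_dndlogdp(theta: np.ndarray, logd: np.ndarray) -> np.ndarray:
    p = _unpack(theta)  # columns: N, gmd, s = log10(gsd)
    n, gmd, s = p[:, 0], p[:, 1], p[:, 2]
    z = (logd[:, None] - np.log10(gmd)[None, :]) / s[None, :]
    return ((n[None, :] / (_SQRT2PI * s[None, :])) * np.exp(-0.5 * z * z)).sum(axis=1)


@dataclass
class MultiLognormalResults:
    """Fitted multi-lognormal decomposition of one distribution."""

    modes: list  # LognormalMode, sorted by ascending gmd
    n_modes: int
    bic: float
    bic_by_k: dict
    r_squared: float
    rss_log: float
    converged: bool
    grid: SizeGrid
    observed: np.ndarray

    @property
    def fitted(self) -> np.ndarray:
        return evaluate_modes(self.modes, self.grid)

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.fitted

    def summary(self) -> str:
        lines = [
            "Multi-lognormal fit",
            f"  modes selected : {self.n_modes} (BIC {self.bic:.1f})",
            f"  R^2 (linear)   : {self.r_squared:.4f}",
            f"  converged      : {self.converged}",
            f"  {'mode':>4} {'N [cm^-3]':>12} {'gmd [nm]':>10} {'gsd':>6}",
        ]
        for i, m in enumerate(self.modes, 1):
            lines.append(f"  {i:>4} {m.number:>12.1f} {m.gmd:>10.2f} {m.gsd:>6.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the observed distribution, the fit and its modes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.grid.mid_diameters_nm
        ax.plot(d, self.observed, "k.", label="observed")
        ax.plot(d, self.fitted, "r-", label=f"fit ({self.n_modes} modes)")
        for m in self.modes:
            ax.plot(d, evaluate_modes([m], self.grid), "--", alpha=0.6)
        ax.set_xscale("log")
        ax.set_xlabel("$d_p$ [nm]")
        ax.set_ylabel("dN/dlog$_{10}d_p$ [cm$^{-3}$]")
        ax.legend()
        return ax


class MultiLognormalModel:
    """Bounded least-squares multi-lognormal fit with BIC mode selection.

    Fitting is done on log10(dN/dlogd_p + eps) with eps = 0.1 cm^-3 to
    stabilise low tails.  Initial mode positions come from local maxima of
    the smoothed distribution; a few seeded jittered restarts guard
    against bad starts.  The mode count is chosen by BIC over
    1..max_modes; modes are returned sorted by ascending gmd.

    Parameters
    ----------
    dndlogdp : array
        Observed dN/dlog10(d_p) per bin (cm^-3), non-negative, not all zero.
    grid : SizeGrid
    max_modes : int, 1..4
    eps : float
        Floor added before taking log10 (cm^-3).
    """

    #: optimisation bounds, log10-space: N [cm^-3], gmd [nm], log10(gsd)
    N_BOUNDS = (1e-3, 1e7)
    GSD_BOUNDS = (1.05, 3.2)

    def __init__(self, dndlogdp, grid: SizeGrid, max_modes: int = 3, eps: float = 0.1,
                 n_restarts: int = 3, seed: int = 0):
        y = np.asarray(dndlogdp, dtype=float)
        if y.shape != (grid.n_bins,):
            raise ValueError("dndlogdp length must match grid")
        if np.any(y < 0):
            raise ValueError("dndlogdp must be non-negative")
        if not np.any(y > 0):
            raise ValueError("cannot fit an all-zero distribution")
        if not 1 <= max_modes <= 4:
            raise ValueError("max_modes must be in 1..4")
        self.y = y
        self.grid = grid
        self.max_modes = max_modes
        self.eps = eps
        self.n_restarts = n_restarts
        self.seed = seed
        # gmd may sit half a decade past either grid edge (truncated modes)
        dmin, dmax = grid.mid_diameters_nm[0], grid.mid_diameters_nm[-1]
        self.gmd_bounds = (dmin / 10 ** 0.5, dmax * 10 ** 0.5)

    # -- initialisation -------------------------------------------------

    def _initial_gmds(self, k: int) -> np.ndarray:
        y = self.y
        d = self.grid.mid_diameters_nm
        win = min(7, y.size if y.size % 2 == 1 else y.size - 1)
        smooth = signal.savgol_filter(np.log10(y + self.eps), win, 2) if win >= 5 else np.log10(y + self.eps)
        peaks, props = signal.find_peaks(smooth, prominence=0.02)
        order = np.argsort(props["prominences"])[::-1] if peaks.size else np.array([], int)
        gmds = list(d[peaks[order][:k]])
        if len(gmds) < k:
            # fill with quantile positions of the number distribution
            w = y * self.grid.dlog
            cdf = np.cumsum(w) / w.sum()
            want = np.linspace(0.15, 0.85, k)
            for q in want:
                cand = d[np.searchsorted(cdf, q)]
                if all(abs(np.log10(cand / g)) > 0.08 for g in gmds):
                    gmds.append(cand)
                if len(gmds) == k:
                    break
            while len(gmds) < k:
                gmds.append(float(np.exp(np.mean(np.log(d)))))
        return np.sort(np.asarray(gmds[:k], dtype=float))

    def _initial_params(self, k: int, rng: np.random.Generator | None) -> np.ndarray:
        gmds = self._initial_gmds(k)
        logd = np.log10(self.grid.mid_diameters_nm)
        s0 = np.log10(1.6)
        params = []
        for g in gmds:
            idx = int(np.argmin(np.abs(logd - np.log10(g))))
            n0 = max(self.y[idx] * _SQRT2PI * s0, 10 * self.eps)
            params.append([n0, g, s0])
        p = np.asarray(params)
        if rng is not None:
            p[:, 0] *= 10 ** rng.normal(0, 0.15, k)
            p[:, 1] *= 10 ** rng.normal(0, 0.05, k)
        return p

    # -- fitting --------------------------------------------------------

    def _fit_k(self, k: int) -> tuple[np.ndarray, float, bool]:
        logd = np.log10(self.grid.mid_diameters_nm)
        target = np.log10(self.y + self.eps)

        def resid(theta):
            return np.log10(_model_dndlogdp(theta, logd) + self.eps) - target

        lo = np.tile(np.log10([self.N_BOUNDS[0], self.gmd_bounds[0], np.log10(self.GSD_BOUNDS[0])]), k)
        hi = np.tile(np.log10([self.N_BOUNDS[1], self.gmd_bounds[1], np.log10(self.GSD_BOUNDS[1])]), k)
        best = None
        rng = np.random.default_rng(self.seed)
        for r in range(self.n_restarts + 1):
            p0 = self._initial_params(k, rng if r else None)
            theta0 = np.clip(_pack(p0), lo, hi)
            try:
                sol = optimize.least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                                             xtol=1e-12, ftol=1e-12, max_nfev=4000)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[1] - 1e-12:
                best = (sol.x, rss, bool(sol.success))
            if best[1] < 1e-16:
                break
        if best is None:
            raise RuntimeError("least-squares optimisation failed for all starts")
        return best

    def fit(self) -> MultiLognormalResults:
        n = self.y.size
        results = {}
        for k in range(1, self.max_modes + 1):
            if 3 * k >= n:
                break
            theta, rss, ok = self._fit_k(k)
            # relative floor: an exact fit must not reward extra modes
            floor = 1e-12 * n
            bic = n * np.log(max(rss, floor) / n) + 3 * k * np.log(n)
            results[k] = (theta, rss, ok, bic)
        k_best = min(results, key=lambda k: results[k][3])
        theta, rss, ok, bic = results[k_best]
        p = _unpack(theta)
        modes = sorted(
            (LognormalMode(number=row[0], gmd=row[1], gsd=10 ** row[2]) for row in p),
            key=lambda m: m.gmd,
        )
        fitted = evaluate_modes(modes, self.grid)
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((self.y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return MultiLognormalResults(
            modes=modes,
            n_modes=k_best,
            bic=bic,
            bic_by_k={k: v[3] for k, v in results.items()},
            r_squared=r2,
            rss_log=rss,
            converged=ok,
            grid=self.grid,
            observed=self.y,
        )


def fit_multilognormal(dndlogdp, grid: SizeGrid, max_modes: int = 3, **kw) -> MultiLognormalResults:
    """Convenience wrapper: ``MultiLognormalModel(...).fit()``."""
    return MultiLognormalModel(dndlogdp, grid, max_modes=max_modes, **kw).fit()
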