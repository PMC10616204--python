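"""Exposure-response layer: endpoint computation and statistical models.

Covers the toxicological side of the pipeline: 2^-ddCt fold changes for
the marker genes (HMOX-1, CXCL-8), mass-normalisation of oxidative
potential (OP) and particle-bound ROS metrics, the pairwise Pearson /
Spearman correlation matrix across daily aerosol and response variables,
the multilinear model of fold change on total OP plus size-banded
condensation sinks, and a continuous segmented (two-piece linear)
concentration-response fit with a grid-searched breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "fold_change_ddct",
    "FoldChange",
    "normalize_op",
    "ros_mass_norm",
    "correlation_matrix",
    "CorrelationMatrices",
    "OPCSModel",
    "OPCSResults",
    "SegmentedResponseModel",
    "SegmentedResponseResults",
]


# -- fold changes ------------------------------------------------------------


@dataclass(frozen=True)
class FoldChange:
    """Replicate-aggregated 2^-ddCt fold change."""

    value: float  # geometric mean over replicates
    sd: float  # sd of replicate fold changes
    n: int  # replicates used
    flagged: bool  # True when replicates were dropped as missing


def fold_change_ddct(ct_target_exp, ct_ref_exp, ct_target_ctl, ct_ref_ctl) -> FoldChange:
    """Fold change by the 2^-ddCt convention.

    ddCt = (Ct_target - Ct_ref)_exposed - (Ct_target - Ct_ref)_control,
    fold change = 2^-ddCt.  Inputs may be scalars or replicate arrays
    (aligned element-wise, e.g. qPCR triplicates); replicates with any
    missing Ct are dropped and the result flagged.  The aggregate is the
    geometric mean of the replicate fold changes with the sd of the
    replicate fold changes.
    """
    arrs = [np.atleast_1d(np.asarray(a, dtype=float))
            for a in (ct_target_exp, ct_ref_exp, ct_target_ctl, ct_ref_ctl)]
    n = max(a.size for a in arrs)
    arrs = [np.full(n, a[0]) if a.size == 1 else a for a in arrs]
    if any(a.size != n for a in arrs):
        raise ValueError("replicate arrays must have equal length (or be scalar)")
    ok = ~np.any([np.isnan(a) | np.isinf(a) for a in arrs], axis=0)
    if not ok.any():
        raise ValueError("no complete replicate")
    te, re_, tc, rc = (a[ok] for a in arrs)
    ddct = (te - re_) - (tc - rc)
    fc = 2.0 ** (-ddct)
    value = float(np.exp(np.mean(np.log(fc))))
    sd = float(np.std(fc, ddof=1)) if fc.size > 1 else 0.0
    return FoldChange(value=value, sd=sd, n=int(ok.sum()), flagged=bool((~ok).any()))


# -- OP / ROS normalisations -------------------------------------------------


def normalize_op(dtt_v, pm1):
    """Intrinsic (mass-normalised) OP: DTTm = DTTv / PM1.

    DTTv in nmol DTT min^-1 m^-3 and PM1 in ug m^-3 give DTTm in
    nmol DTT min^-1 ug^-1.  PM1 <= 0 yields NaN (flagged missing).
    """
    v = np.asarray(dtt_v, dtype=float)
    m = np.asarray(pm1, dtype=float)
    out = np.where(m > 0, v / np.where(m > 0, m, np.nan), np.nan)
    return float(out) if out.ndim == 0 else out


def ros_mass_norm(ros_v, pm1):
    """Mass-normalised particle-bound ROS (nmol H2O2 ug^-1); same rule as OP."""
    return normalize_op(ros_v, pm1)


# -- correlation matrix ------------------------------------------------------


@dataclass
class CorrelationMatrices:
    """Pairwise-complete Pearson R^2 / Spearman rho^2 with p-values and n."""

    r2: pd.DataFrame
    rho2: pd.DataFrame
    p_pearson: pd.DataFrame
    p_spearman: pd.DataFrame
    n: pd.DataFrame

    def apply_bh(self, alpha: float = 0.05) -> pd.DataFrame:
        """Benjamini-Hochberg adjusted Pearson p-values (off-diagonal)."""
        from statsmodels.stats.multitest import multipletests

        p = self.p_pearson.copy()
        cols = p.columns
        iu = np.triu_indices(len(cols), k=1)
        raw = p.to_numpy()[iu]
        ok = ~np.isnan(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = multipletests(raw[ok], alpha=alpha, method="fdr_bh")[1]
        out = np.full(p.shape, np.nan)
        out[iu] = adj
        out.T[iu] = adj
        np.fill_diagonal(out, 0.0)
        return pd.DataFrame(out, index=cols, columns=cols)


def correlation_matrix(table: pd.DataFrame, variables=None, min_n: int = 4) -> CorrelationMatrices:
    """Fig.-1-style pairwise correlation matrices (two-sided p-values).

    Pairwise-complete observations; pairs with fewer than ``min_n``
    points, or with a zero-variance member, get NaN entries.  Spearman
    uses mid-ranks for ties.
    """
    cols = list(variables) if variables is not None else list(table.columns)
    k = len(cols)
    r2 = np.full((k, k), np.nan)
    rho2 = np.full((k, k), np.nan)
    pp = np.full((k, k), np.nan)
    ps = np.full((k, k), np.nan)
    nn = np.zeros((k, k), dtype=int)
    for i in range(k):
        r2[i, i] = rho2[i, i] = 1.0
        pp[i, i] = ps[i, i] = 0.0
        nn[i, i] = table[cols[i]].notna().sum()
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            n = len(pair)
            nn[i, j] = nn[j, i] = n
            if n < min_n:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p_r = stats.pearsonr(x, y)
            rho, p_s = stats.spearmanr(x, y)
            r2[i, j] = r2[j, i] = r * r
            pp[i, j] = pp[j, i] = p_r
            rho2[i, j] = rho2[j, i] = rho * rho
            ps[i, j] = ps[j, i] = p_s
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationMatrices(r2=mk(r2), rho2=mk(rho2), p_pearson=mk(pp),
                               p_spearman=mk(ps), n=mk(nn))


# -- multilinear OP x CS model -----------------------------------------------


class OPCSModel:
    """OLS of an endpoint on standardized OP and condensation-sink bands.

    Predictors are z-scored before fitting so coefficient signs and
    magnitudes are directly comparable; an intercept is always included.

    Parameters
    ----------
    endog : Series or array
        Response (e.g. HMOX-1 fold change), one value per day.
    exog : DataFrame
        Predictor columns (e.g. ``dtt_v``, ``cs_200_900``).
    """

    COND_WARN = 30.0  # condition number above which collinearity is flagged

    def __init__(self, endog, exog: pd.DataFrame):
        y = np.asarray(endog, dtype=float)
        X = pd.DataFrame(exog).astype(float)
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        if len(y) < X.shape[1] + 3:
            raise ValueError(f"need n > predictors + 2 ({len(y)} rows, {X.shape[1]} predictors)")
        sd = X.std(ddof=0)
        if (sd == 0).any():
            raise ValueError(f"zero-variance predictors: {list(sd.index[sd == 0])}")
        self.endog = y
        self.exog = X
        self.exog_z = (X - X.mean()) / sd

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, response: str, predictors) -> "OPCSModel":
        sub = table[[response, *predictors]].dropna()
        return cls(sub[response], sub[list(predictors)])

    def fit(self) -> "OPCSResults":
        X = sm.add_constant(self.exog_z)
        res = sm.OLS(self.endog, X).fit()
        cond = float(np.linalg.cond(X.to_numpy()))
        vif = {}
        if cond > self.COND_WARN and self.exog_z.shape[1] > 1:
            from statsmodels.stats.outliers_influence import variance_inflation_factor

            arr = X.to_numpy()
            vif = {c: float(variance_inflation_factor(arr, i + 1))
                   for i, c in enumerate(self.exog_z.columns)}
        return OPCSResults(self, res, cond, vif)


@dataclass
class OPCSResults:
    """Fit of the multilinear OP+CS response model."""

    model: OPCSModel
    _sm: object
    condition_number: float
    vif: dict

    @property
    def params(self) -> pd.Series:
        return self._sm.params

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def nobs(self) -> int:
        return int(self._sm.nobs)

    @property
    def coefficient_signs(self) -> dict:
        return {c: int(np.sign(self.params[c])) for c in self.model.exog_z.columns}

    @property
    def collinearity_warning(self) -> bool:
        return self.condition_number > OPCSModel.COND_WARN

    def permutation_r2(self, n_permutations: int = 500, seed: int = 0) -> np.ndarray:
        """R^2 of refits with the response permuted (null distribution)."""
        rng = np.random.default_rng(seed)
        X = sm.add_constant(self.model.exog_z)
        out = np.empty(n_permutations)
        y = self.model.endog
        for i in range(n_permutations):
            out[i] = sm.OLS(rng.permutation(y), X).fit().rsquared
        return out

    def summary(self):
        return self._sm.summary()


# -- segmented concentration-response ---------------------------------------


class SegmentedResponseModel:
    """Continuous two-piece linear concentration-response fit.

    y = b0 + s1 * x + (s2 - s1) * max(0, x - psi), with the breakpoint
    psi grid-searched (default 1 ug/m^3 steps over [5, 40]) and the
    segmented-vs-linear choice made by BIC.  Grid points with fewer than
    ``min_side`` observations on either side are skipped; if none remain
    the fit falls back to a single line (flagged).
    """

    def __init__(self, x, y, breakpoint_grid=None, min_side: int = 3):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 8:
            raise ValueError("need at least 8 points for a segmented fit")
        self.x, self.y = x, y
        self.grid = (np.arange(5.0, 40.0 + 1e-9, 1.0) if breakpoint_grid is None
                     else np.asarray(breakpoint_grid, dtype=float))
        self.min_side = min_side

    def _bic(self, rss: float, n: int, k: int) -> float:
        # floor the RSS at a relative scale so that numerically-zero
        # residuals (exact fits) do not reward extra parameters
        floor = 1e-10 * n * max(float(np.var(self.y)), 1e-30)
        return n * np.log(max(rss, floor) / n) + k * np.log(n)

    def fit(self) -> "SegmentedResponseResults":
        x, y, n = self.x, self.y, self.x.size
        X_lin = np.column_stack([np.ones(n), x])
        beta_lin, rss_lin = _ols(X_lin, y)
        bic_lin = self._bic(rss_lin, n, 2)

        best = None
        for psi in self.grid:
            if (x < psi).sum() < self.min_side or (x >= psi).sum() < self.min_side:
                continue
            X = np.column_stack([np.ones(n), x, np.maximum(0.0, x - psi)])
            beta, rss = _ols(X, y)
            if best is None or rss < best[1]:
                best = (psi, rss, beta)
        if best is None:
            return SegmentedResponseResults(
                breakpoint=np.nan, slope1=float(beta_lin[1]), slope2=float(beta_lin[1]),
                intercept=float(beta_lin[0]), bic_segmented=np.nan, bic_linear=bic_lin,
                prefers_segmented=False, fallback_linear=True, n=n, x=x, y=y,
            )
        psi, rss, beta = best
        bic_seg = self._bic(rss, n, 4)  # intercept, slope1, slope change, breakpoint
        return SegmentedResponseResults(
            breakpoint=float(psi), slope1=float(beta[1]), slope2=float(beta[1] + beta[2]),
            intercept=float(beta[0]), bic_segmented=bic_seg, bic_linear=bic_lin,
            prefers_segmented=bool(bic_seg < bic_lin), fallback_linear=False, n=n, x=x, y=y,
        )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class SegmentedResponseResults:
    """Breakpoint, the two slopes, and the segmented-vs-linear comparison."""

    breakpoint: float  # ug/m^3 (NaN when fallen back to linear)
    slope1: float  # slope below the breakpoint
    slope2: float  # slope above the breakpoint
    intercept: float
    bic_segmented: float
    bic_linear: float
    prefers_segmented: bool
    fallback_linear: bool
    n: int
    x: np.ndarray
    y: np.ndarray

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.fallback_linear:
            return self.intercept + self.slope1 * x
        return (self.intercept + self.slope1 * x
                + (self.slope2 - self.slope1) * np.maximum(0.0, x - self.breakpoint))

    def summary(self) -> str:
        lines = [
            "Segmented concentration-response fit",
            f"  n                : {self.n}",
            f"  breakpoint       : {self.breakpoint:.1f} ug/m^3" if not self.fallback_linear
            else "  breakpoint       : (linear fallback)",
            f"  slope below/above: {self.slope1:.4g} / {self.slope2:.4g}",
            f"  BIC segmented    : {self.bic_segmented:.2f}",
            f"  BIC linear       : {self.bic_linear:.2f}",
            f"  preferred model  : {'segmented' if self.prefers_segmented else 'linear'}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, "ko", ms=4)
        xs = np.linspace(self.x.min(), self.x.max(), 200)
        ax.plot(xs, self.predict(xs), "r-")
        if not self.fallback_linear:
            ax.axvline(self.breakpoint, ls="--", color="gray")
        ax.set_xlabel("PM$_1$ [$\\mu$g m$^{-3}$]")
        ax.set_ylabel("fold change")
        return ax
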