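"""Synthetic urban aerosol campaigns with full ground truth.

Generates PNSD time series, co-measured covariates and gene-expression
endpoints with the statistical structure the analysis layer assumes,
for three urban aerosol archetypes:

- ``urban_fresh``: traffic aerosol — a dominant 18 nm nucleation mode
  (gsd 1.6) following a weekday rush-hour schedule, a minor 48 nm mode,
  a weak accumulation background; high BC-to-OA and strong Cu/DTT
  coupling.
- ``urban_aged``: stagnation aerosol — a dominant 250 nm accumulation
  mode, low BC-to-OA, high PM1 (day-to-day amplitude ramps emulate
  multi-day accumulation episodes).
- ``regional_npf``: regional photonucleation — a midday 18 nm mode whose
  diameter grows through the afternoon, weak combustion covariates and
  low OP coupling.

Couplings: per 10-min record the distribution is the schedule-modulated
mode evaluation times multiplicative lognormal bin noise; eBC and
insoluble Cu follow the combustion-intensity schedule; daily total OP is
DTTv = alpha*Cu + beta*N_8-20 + gamma*PM1 + noise; gene fold changes are
fc = max(eps, 1 + a*z(DTTv) + b*z(CS_8-20) - c*z(CS_200-900) + noise).

All magnitudes are calibration constants of the generator (configurable,
never measurements), chosen so daily PM1 spans roughly 2-60 ug/m^3
across the three archetypes and the daily covariates show the canonical
urban correlation pattern.  Randomness is fully deterministic given the
seed, with independent sub-streams for PNSD noise, covariate noise,
reference-measurement noise and response noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import DensityModel, SizeGrid, make_size_grid
from .lognormal import LognormalMode, evaluate_modes
from .pnsd import MAC_880_M2_PER_G, integrate_number, pm_mass_from_pnsd

__all__ = [
    "ScheduledMode",
    "ScenarioConfig",
    "GeneResponseConfig",
    "scenario_presets",
    "winter_assignment",
    "simulate_campaign",
    "simulate_response",
    "Campaign",
    "CampaignTruth",
]


# -- schedules (hour-of-week multipliers, Monday 00:00 -> Sunday 23:00) ------


def rush_hour_schedule(base=0.15, day=0.5, rush=1.0, weekend=0.05) -> np.ndarray:
    """Weekday rush-hour traffic schedule; quiet on the weekend."""
    s = np.full(168, weekend)
    for dow in range(5):
        for h in range(24):
            if h in (7, 8, 9, 17, 18, 19):
                s[dow * 24 + h] = rush
            elif 10 <= h <= 16:
                s[dow * 24 + h] = day
            else:
                s[dow * 24 + h] = base
    return s


def flat_schedule(level: float = 1.0) -> np.ndarray:
    return np.full(168, level)


def midday_schedule(base=0.05, peak=1.0) -> np.ndarray:
    """Photochemistry-driven midday window, every day of the week."""
    s = np.full(168, base)
    for dow in range(7):
        for h in range(10, 17):
            s[dow * 24 + h] = peak
    return s


@dataclass(frozen=True)
class ScheduledMode:
    """A lognormal mode with an hour-of-week activity schedule.

    ``gmd_growth_per_h`` shifts the geometric mean diameter by that
    factor per hour after ``growth_onset_hour`` (local), emulating NPF
    growth through the afternoon.
    """

    mode: LognormalMode
    schedule: np.ndarray  # 168 multipliers >= 0
    gmd_growth_per_h: float = 0.0  # fractional gmd increase per hour
    growth_onset_hour: int = 10

    def __post_init__(self) -> None:
        s = np.asarray(self.schedule, dtype=float)
        if s.shape != (168,) or np.any(s < 0):
            raise ValueError("schedule must be 168 non-negative hour-of-week multipliers")
        object.__setattr__(self, "schedule", s)

    def at(self, ts: pd.Timestamp, amplitude: float = 1.0) -> LognormalMode:
        """The effective mode at timestamp ts (may have number == 0)."""
        how = ts.dayofweek * 24 + ts.hour
        mult = self.schedule[how] * amplitude
        gmd = self.mode.gmd
        if self.gmd_growth_per_h > 0 and ts.hour >= self.growth_onset_hour and mult > 0:
            hours = ts.hour + ts.minute / 60.0 - self.growth_onset_hour
            gmd = gmd * (1.0 + self.gmd_growth_per_h * hours)
        return LognormalMode(number=self.mode.number * mult, gmd=gmd, gsd=self.mode.gsd)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for one aerosol archetype."""

    name: str
    modes: tuple  # ScheduledMode, ...
    bc_to_oa: float  # freshness proxy, < 0.5 throughout
    combustion_schedule: np.ndarray  # hour-of-week intensity (dimensionless)
    ebc_scale: float  # ug/m^3 eBC per unit combustion intensity
    cu_scale: float  # ng/m^3 insoluble Cu per unit daily intensity
    dtt_alpha_cu: float  # nmol/min/m^3 per ng/m^3 Cu
    dtt_beta_n820: float  # nmol/min/m^3 per cm^-3 N_8-20
    dtt_gamma_pm1: float  # nmol/min/m^3 per ug/m^3 PM1
    dtt_noise_sd: float = 0.08  # lognormal sd of daily DTTv
    ws_dtt_fraction: float = 0.55
    ros_per_dtt: float = 0.6  # nmol H2O2 m^-3 per nmol DTT min^-1 m^-3
    pnsd_noise_sd: float = 0.10  # multiplicative lognormal bin noise
    covariate_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        s = np.asarray(self.combustion_schedule, dtype=float)
        if s.shape != (168,) or np.any(s < 0):
            raise ValueError("combustion_schedule must be 168 non-negative multipliers")
        object.__setattr__(self, "combustion_schedule", s)


def scenario_presets() -> dict:
    """The three packaged archetypes (see module docstring)."""
    rush = rush_hour_schedule()
    fresh = ScenarioConfig(
        name="urban_fresh",
        modes=(
            ScheduledMode(LognormalMode(8000.0, 18.0, 1.6), rush),
            ScheduledMode(LognormalMode(1500.0, 48.0, 1.7), rush_hour_schedule(base=0.25, day=0.6)),
            ScheduledMode(LognormalMode(250.0, 150.0, 1.6), flat_schedule(1.0)),
        ),
        bc_to_oa=0.35,
        combustion_schedule=rush,
        ebc_scale=1.5,
        cu_scale=8.0,
        dtt_alpha_cu=0.05,
        dtt_beta_n820=4.0e-4,
        dtt_gamma_pm1=0.02,
    )
    aged = ScenarioConfig(
        name="urban_aged",
        modes=(
            ScheduledMode(LognormalMode(800.0, 250.0, 1.6), flat_schedule(1.0)),
            ScheduledMode(LognormalMode(1200.0, 70.0, 1.8), flat_schedule(1.0)),
            ScheduledMode(LognormalMode(200.0, 20.0, 1.5), rush_hour_schedule(base=0.1, day=0.3, rush=0.5)),
        ),
        bc_to_oa=0.10,
        combustion_schedule=flat_schedule(0.5),
        ebc_scale=2.0,
        cu_scale=3.0,
        dtt_alpha_cu=0.05,
        dtt_beta_n820=4.0e-4,
        dtt_gamma_pm1=0.02,
    )
    npf = ScenarioConfig(
        name="regional_npf",
        modes=(
            ScheduledMode(LognormalMode(6000.0, 18.0, 1.5), midday_schedule(),
                          gmd_growth_per_h=0.15, growth_onset_hour=10),
            ScheduledMode(LognormalMode(400.0, 200.0, 1.6), flat_schedule(1.0)),
        ),
        bc_to_oa=0.15,
        combustion_schedule=flat_schedule(0.3),
        ebc_scale=0.5,
        cu_scale=1.0,
        dtt_alpha_cu=0.02,
        dtt_beta_n820=5.0e-5,
        dtt_gamma_pm1=0.015,
    )
    return {c.name: c for c in (fresh, aged, npf)}


def winter_assignment() -> list:
    """The packaged 16-day campaign: four 4-day Tuesday-to-Saturday blocks.

    Two traffic-dominated blocks, one multi-day stagnation/accumulation
    episode with a ramping amplitude, and one regional-NPF block.
    """
    return (
        [("urban_fresh", a) for a in (1.0, 1.2, 0.9, 1.1)]
        + [("urban_aged", a) for a in (0.3, 0.9, 1.6, 2.3)]
        + [("urban_fresh", a) for a in (0.8, 1.0, 1.3, 1.1)]
        + [("regional_npf", a) for a in (1.0, 1.1, 0.9, 1.0)]
    )


@dataclass
class CampaignTruth:
    """Generator ground truth for every downstream test."""

    record_modes: pd.DataFrame  # timestamp, mode index, N, gmd, gsd (noiseless)
    noiseless_pnsd: pd.DataFrame
    daily_true_pm1: pd.Series
    daily_true_dttv: pd.Series  # noiseless DTTv signal
    day_scenario: pd.Series  # scenario name per 08:00-anchored day
    day_amplitude: pd.Series
    seeds: dict


@dataclass
class Campaign:
    """One synthetic campaign: observations plus ground truth."""

    pnsd: pd.DataFrame  # dN/dlog10 dp, cm^-3 (10-min cadence)
    grid: SizeGrid
    covariates_10min: pd.DataFrame  # b_abs_880_Mm, ebc, oa
    daily_covariates: pd.DataFrame  # cu_insoluble, dtt_v, ws_dtt_v, ros_v, bc_to_oa
    truth: CampaignTruth
    seed: int

    def reference_daily_pm1(self, noise_sd: float = 0.02) -> pd.Series:
        """Simulated reference gravimetric daily PM1: truth x lognormal noise."""
        rng = np.random.default_rng(self.truth.seeds["reference"])
        noise = np.exp(rng.normal(0.0, noise_sd, len(self.truth.daily_true_pm1)))
        return self.truth.daily_true_pm1 * noise


# -- campaign generation ------------------------------------------------------

_START = "2021-01-26 08:00"  # a Tuesday, 08:00 local


def simulate_campaign(assignment=None, scenarios: dict | None = None, dt_min: int = 10,
                      seed: int = 0, grid: SizeGrid | None = None,
                      start: str = _START) -> Campaign:
    """Generate a multi-day campaign.

    assignment : list of (scenario_name, amplitude) — one entry per
    08:00-anchored day (default: the packaged 16-day winter campaign).
    Deterministic given ``seed``; PNSD, covariate, reference and response
    noise use independent RNG sub-streams.
    """
    if (24 * 60) % dt_min != 0:
        raise ValueError("dt_min must divide 24 h")
    assignment = assignment if assignment is not None else winter_assignment()
    scenarios = scenarios or scenario_presets()
    for name, amp in assignment:
        if name not in scenarios:
            raise ValueError(f"unknown scenario {name!r}")
        if amp < 0:
            raise ValueError("day amplitude must be >= 0")
    grid = grid or make_size_grid(8, 1000, 16)

    ss = np.random.SeedSequence(seed)
    child = dict(zip(("pnsd", "covariates", "reference", "response"), ss.spawn(4)))
    seeds = {k: int(v.generate_state(1)[0] % (2**31)) for k, v in child.items()}
    rng_pnsd = np.random.default_rng(child["pnsd"])
    rng_cov = np.random.default_rng(child["covariates"])

    per_day = 24 * 60 // dt_min
    t0 = pd.Timestamp(start)
    index = pd.date_range(t0, periods=per_day * len(assignment), freq=f"{dt_min}min")

    n_bins = grid.n_bins
    clean = np.zeros((len(index), n_bins))
    mode_rows = []
    ebc = np.zeros(len(index))
    day_names, day_amps, day_starts = [], [], []
    for d, (name, amp) in enumerate(assignment):
        cfg = scenarios[name]
        day_names.append(name)
        day_amps.append(amp)
        day_starts.append(t0 + pd.Timedelta(days=d))
        for i in range(per_day):
            row = d * per_day + i
            ts = index[row]
            eff = [sm.at(ts, amp) for sm in cfg.modes]
            clean[row] = evaluate_modes([m for m in eff if m.number > 0], grid)
            for j, m in enumerate(eff):
                mode_rows.append((ts, j, m.number, m.gmd, m.gsd))
            how = ts.dayofweek * 24 + ts.hour
            intensity = cfg.combustion_schedule[how] * amp
            ebc[row] = max(
                cfg.ebc_scale * intensity
                * np.exp(rng_cov.normal(0.0, cfg.covariate_noise_sd)),
                0.0,
            )

    noise_sds = np.repeat([scenarios[n].pnsd_noise_sd for n, _ in assignment], per_day)
    noise = np.exp(rng_pnsd.normal(0.0, 1.0, clean.shape) * noise_sds[:, None])
    pnsd = pd.DataFrame(clean * noise, index=index,
                        columns=[f"{d:.3f}" for d in grid.mid_diameters_nm])
    pnsd.index.name = "timestamp"

    bc_to_oa = np.repeat([scenarios[n].bc_to_oa for n, _ in assignment], per_day)
    oa = ebc / bc_to_oa
    cov10 = pd.DataFrame(
        {"b_abs_880_Mm": ebc * MAC_880_M2_PER_G, "ebc": ebc, "oa": oa},
        index=index,
    )

    # ---- daily covariates (filters are 08:00 -> 08:00 integrals) ----
    day_index = pd.DatetimeIndex(day_starts, name="window_start")
    daily_true_pm1, daily_n820, cu, dttv_true, dttv = [], [], [], [], []
    ws_dtt, ros_v, bc_oa_daily = [], [], []
    for d, (name, amp) in enumerate(assignment):
        cfg = scenarios[name]
        sl = slice(d * per_day, (d + 1) * per_day)
        pm1_true = float(np.mean(pm_mass_from_pnsd(clean[sl], grid)))
        n820 = float(np.mean(integrate_number(clean[sl], grid, 8, 20)))
        how = index[sl].dayofweek * 24 + index[sl].hour
        intensity = float(np.mean(cfg.combustion_schedule[how])) * amp
        cu_d = max(cfg.cu_scale * intensity
                   * np.exp(rng_cov.normal(0.0, cfg.covariate_noise_sd)), 0.0)
        signal = (cfg.dtt_alpha_cu * cu_d + cfg.dtt_beta_n820 * n820
                  + cfg.dtt_gamma_pm1 * pm1_true)
        dtt_d = signal * np.exp(rng_cov.normal(0.0, cfg.dtt_noise_sd))
        daily_true_pm1.append(pm1_true)
        daily_n820.append(n820)
        cu.append(cu_d)
        dttv_true.append(signal)
        dttv.append(dtt_d)
        ws_dtt.append(cfg.ws_dtt_fraction * dtt_d
                      * np.exp(rng_cov.normal(0.0, 0.05)))
        ros_v.append(cfg.ros_per_dtt * dtt_d
                     * np.exp(rng_cov.normal(0.0, 0.10)))
        bc_oa_daily.append(cfg.bc_to_oa)

    daily_cov = pd.DataFrame(
        {
            "cu_insoluble": cu,
            "dtt_v": dttv,
            "ws_dtt_v": ws_dtt,
            "ros_v": ros_v,
            "bc_to_oa_true": bc_oa_daily,
        },
        index=day_index,
    )

    truth = CampaignTruth(
        record_modes=pd.DataFrame(mode_rows,
                                  columns=["timestamp", "mode", "number", "gmd", "gsd"]),
        noiseless_pnsd=pd.DataFrame(clean, index=index, columns=pnsd.columns),
        daily_true_pm1=pd.Series(daily_true_pm1, index=day_index, name="pm1_true"),
        daily_true_dttv=pd.Series(dttv_true, index=day_index, name="dtt_v_true"),
        day_scenario=pd.Series(day_names, index=day_index, name="scenario"),
        day_amplitude=pd.Series(day_amps, index=day_index, name="amplitude"),
        seeds=seeds,
    )
    return Campaign(pnsd=pnsd, grid=grid, covariates_10min=cov10,
                    daily_covariates=daily_cov, truth=truth, seed=seed)


# -- gene response ------------------------------------------------------------


@dataclass(frozen=True)
class GeneResponseConfig:
    """Linear response of one gene's fold change to OP and CS bands."""

    a_op: float  # coefficient on z(DTTv)
    b_cs_nucleation: float  # coefficient on z(CS_8-20)
    c_cs_accumulation: float  # subtracted coefficient on z(CS_200-900), > 0
    noise_sd: float = 0.12
    replicate_sd: float = 0.08  # lognormal spread of simulated qPCR triplicates
    floor: float = 0.05


DEFAULT_GENES = {
    "hmox1": GeneResponseConfig(a_op=0.45, b_cs_nucleation=0.15, c_cs_accumulation=0.35),
    "cxcl8": GeneResponseConfig(a_op=0.55, b_cs_nucleation=0.20, c_cs_accumulation=0.40),
}


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_response(daily: pd.DataFrame, genes: dict | None = None, seed: int = 0,
                      n_replicates: int = 3):
    """Simulate daily fold changes from a daily table.

    ``daily`` must carry ``dtt_v``, ``cs_8_20`` and ``cs_200_900``
    columns.  Per gene: mean fold change
    fc = max(floor, 1 + a*z(dtt_v) + b*z(cs_8_20) - c*z(cs_200_900) + e),
    then ``n_replicates`` lognormal replicates around it give the
    reported (value, sd, p) triple — p from a two-sided one-sample t-test
    of log(fc) against 0.

    Returns ``(tox_table, truth)``: the table has ``<gene>_fc``,
    ``<gene>_sd``, ``<gene>_p`` columns; truth holds the noiseless means.
    """
    genes = genes or DEFAULT_GENES
    for col in ("dtt_v", "cs_8_20", "cs_200_900"):
        if col not in daily.columns:
            raise ValueError(f"daily table lacks {col!r}")
        if daily[col].isna().any():
            raise ValueError(f"daily table has missing {col!r}")
    rng = np.random.default_rng(seed)
    z_op = _z(daily["dtt_v"].to_numpy(dtype=float))
    z_nuc = _z(daily["cs_8_20"].to_numpy(dtype=float))
    z_acc = _z(daily["cs_200_900"].to_numpy(dtype=float))
    n = len(daily)
    out = {}
    truth = {}
    for gname, g in genes.items():
        mean_fc = 1.0 + g.a_op * z_op + g.b_cs_nucleation * z_nuc - g.c_cs_accumulation * z_acc
        noisy = np.maximum(g.floor, mean_fc + rng.normal(0.0, g.noise_sd, n))
        reps = noisy[:, None] * np.exp(rng.normal(0.0, g.replicate_sd, (n, n_replicates)))
        fc = np.exp(np.mean(np.log(reps), axis=1))
        sd = reps.std(axis=1, ddof=1)
        from scipy import stats as _st

        p = np.array([_st.ttest_1samp(np.log(r), 0.0).pvalue for r in reps])
        out[f"{gname}_fc"] = fc
        out[f"{gname}_sd"] = sd
        out[f"{gname}_p"] = p
        truth[gname] = mean_fc
    tox = pd.DataFrame(out, index=daily.index)
    truth_df = pd.DataFrame(truth, index=daily.index)
    return tox, truth_df
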