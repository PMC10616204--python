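"""End-to-end campaign analysis driver.

Reproduces the standard analysis sequence on any campaign: PNSD ->
condensation-sink bands + N_8-20 + PM1 -> aerosol typing -> 08:00-anchored
daily join with OP/endpoint covariates -> correlation matrix ->
multilinear OP+CS and segmented concentration-response fits -> ALI dose.
Every run emits a provenance block (config hash, seeds, package version)
and is byte-reproducible given config + seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .aerosol_typing import type_campaign
from .condensation import DEFAULT_BAND_EDGES, VaporProperties, cs_bands_series
from .dose import ChamberGeometry, dose_per_area
from .grids import DensityModel, SizeGrid
from .io import read_pnsd_csv, write_daily_csv
from .pnsd import daily_aggregate, integrate_number, pm_mass_from_pnsd
from .response import OPCSModel, SegmentedResponseModel, correlation_matrix, normalize_op

__all__ = ["RunConfig", "daily_table", "run_pipeline"]


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run (serialised to provenance)."""

    pnsd_csv: str
    daily_covariates_csv: str | None = None
    tox_csv: str | None = None
    out_dir: str = "aerotox_out"
    seed: int = 0
    # physics
    vapor_diffusion_m2_s: float = Field(8.0e-6, gt=0)
    vapor_molar_mass_kg_mol: float = Field(0.098, gt=0)
    vapor_temperature_K: float = Field(293.15, gt=0)
    band_edges: tuple = DEFAULT_BAND_EDGES
    rho_min: float = Field(1.25, gt=0)
    rho_max: float = Field(1.5, gt=0)
    mac_m2_g: float = Field(7.77, gt=0)
    # typing
    typing_transform: str = "log10_standardize"
    typing_k: int | None = None
    # dose
    insert_area_cm2: float = Field(1.13, gt=0)
    flow_cm3_min: float = Field(30.0, gt=0)
    deposition_height_cm: float = Field(0.2, gt=0)
    # response
    response_predictors: tuple = ("dtt_v", "cs_8_20", "cs_200_900")
    response_endpoints: tuple = ("hmox1_fc", "cxcl8_fc")
    breakpoint_grid: tuple = (5.0, 40.0, 1.0)  # lo, hi, step (ug/m^3)
    min_daily_coverage: float = 0.75

    def vapor(self) -> VaporProperties:
        return VaporProperties(
            diffusion_coefficient=self.vapor_diffusion_m2_s,
            molar_mass=self.vapor_molar_mass_kg_mol,
            temperature=self.vapor_temperature_K,
        )

    def density(self) -> DensityModel:
        return DensityModel(rho_min=self.rho_min, rho_max=self.rho_max)

    def geometry(self) -> ChamberGeometry:
        return ChamberGeometry(
            insert_area_cm2=self.insert_area_cm2,
            flow_cm3_min=self.flow_cm3_min,
            deposition_height_cm=self.deposition_height_cm,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def daily_table(pnsd: pd.DataFrame, grid: SizeGrid, vapor: VaporProperties | None = None,
                density: DensityModel | None = None, band_edges=DEFAULT_BAND_EDGES,
                covariates_10min: pd.DataFrame | None = None,
                daily_covariates: pd.DataFrame | None = None,
                min_coverage: float = 0.75) -> pd.DataFrame:
    """Build the 08:00-anchored daily aerosol table.

    Columns: pm1, n_tot, n_8_20, the CS bands, coverage/flag, plus daily
    means of any 10-min covariates (ebc, oa -> bc_to_oa) and a join of
    daily covariates (cu_insoluble, dtt_v, ...).  Mass-normalised OP/ROS
    columns (dtt_m, ros_m) are derived where their inputs are present.
    """
    vapor = vapor or VaporProperties()
    density = density or DensityModel()
    values = pnsd.to_numpy(dtype=float)
    per_record = pd.DataFrame(
        {
            "pm1": pm_mass_from_pnsd(values, grid, density),
            "n_tot": integrate_number(values, grid),
            "n_8_20": integrate_number(values, grid, 8, 20),
        },
        index=pnsd.index,
    )
    per_record = per_record.join(cs_bands_series(pnsd, grid, vapor, band_edges))
    agg = daily_aggregate(per_record, min_coverage=min_coverage)
    daily = agg.values.copy()
    daily["coverage"] = agg.coverage
    daily["flagged"] = agg.flagged
    if covariates_10min is not None:
        cov = daily_aggregate(covariates_10min, min_coverage=min_coverage).values
        daily = daily.join(cov, how="left")
        if {"ebc", "oa"} <= set(daily.columns):
            daily["bc_to_oa"] = np.where(daily["oa"] > 0, daily["ebc"] / daily["oa"], np.nan)
    if daily_covariates is not None:
        daily = daily.join(daily_covariates, how="left")
    if {"dtt_v", "pm1"} <= set(daily.columns):
        daily["dtt_m"] = normalize_op(daily["dtt_v"].to_numpy(), daily["pm1"].to_numpy())
    if {"ros_v", "pm1"} <= set(daily.columns):
        daily["ros_m"] = normalize_op(daily["ros_v"].to_numpy(), daily["pm1"].to_numpy())
    return daily


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to config.out_dir.

    Returns a dict of the in-memory results; writes daily_table.csv,
    typing_report.json, labels.csv, correlation_r2.csv, model_fits.json,
    dose_report.json and provenance.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pnsd, grid = read_pnsd_csv(config.pnsd_csv)

    daily_cov = None
    if config.daily_covariates_csv:
        from .io import read_daily_csv

        daily_cov = read_daily_csv(config.daily_covariates_csv)
    tox = None
    if config.tox_csv:
        from .io import read_daily_csv

        tox = read_daily_csv(config.tox_csv)

    daily = daily_table(pnsd, grid, config.vapor(), config.density(),
                        band_edges=config.band_edges, daily_covariates=daily_cov,
                        min_coverage=config.min_daily_coverage)
    if tox is not None:
        daily = daily.join(tox, how="left")
    write_daily_csv(daily, out / "daily_table.csv")

    typing_res = type_campaign(pnsd, grid, seed=config.seed,
                               transform=config.typing_transform, k=config.typing_k)
    (out / "typing_report.json").write_text(json.dumps(typing_res.to_report(), indent=2))
    typing_res.cluster_labels.to_csv(out / "labels.csv")

    numeric = daily.select_dtypes("number").dropna(axis=1, how="all")
    corr = correlation_matrix(numeric)
    corr.r2.to_csv(out / "correlation_r2.csv")
    corr.p_pearson.to_csv(out / "correlation_p.csv")

    fits = {}
    def _band_col(lo, hi):
        return f"cs_{lo:g}_{hi:g}"

    for endpoint in config.response_endpoints:
        if tox is None or endpoint not in daily.columns:
            continue
        preds = [p for p in config.response_predictors if p in daily.columns]
        sub = daily[[endpoint, *preds]].dropna()
        entry = {}
        if len(sub) > len(preds) + 2:
            res = OPCSModel(sub[endpoint], sub[preds]).fit()
            entry["multilinear"] = {
                "predictors": preds,
                "coefficients": {k: float(v) for k, v in res.params.items()},
                "pvalues": {k: float(v) for k, v in res.pvalues.items()},
                "r_squared": res.rsquared,
                "n": res.nobs,
                "collinearity_warning": res.collinearity_warning,
            }
        sub2 = daily[["pm1", endpoint]].dropna()
        if len(sub2) >= 8:
            lo, hi, step = config.breakpoint_grid
            seg = SegmentedResponseModel(sub2["pm1"], sub2[endpoint],
                                         breakpoint_grid=np.arange(lo, hi + 1e-9, step)).fit()
            entry["segmented"] = {
                "breakpoint_ug_m3": seg.breakpoint,
                "slope_low": seg.slope1,
                "slope_high": seg.slope2,
                "prefers_segmented": seg.prefers_segmented,
                "fallback_linear": seg.fallback_linear,
            }
        if entry:
            fits[endpoint] = entry
    (out / "model_fits.json").write_text(json.dumps(fits, indent=2, default=float))

    dose = dose_per_area(pnsd, grid, config.density(), config.geometry())
    (out / "dose_report.json").write_text(json.dumps(dose.as_dict(), indent=2))
    dose.per_bin.to_csv(out / "dose_per_bin.csv", index=False)

    provenance = {
        "package": "aerotox",
        "version": __version__,
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_records": int(len(pnsd)),
        "n_days": int(len(daily)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return {"daily": daily, "typing": typing_res, "correlations": corr,
            "fits": fits, "dose": dose, "provenance": provenance}
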