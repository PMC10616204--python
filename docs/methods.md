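# Methods

`aerotox` implements the aerosol-microphysics and exposure–response
computations used to relate urban particle number size distributions
(PNSDs) to in-vitro oxidative-stress and inflammation endpoints measured
at the air–liquid interface (ALI). This note records the models, their
assumptions, the defaults, and the limits of what the synthetic-data
tests can show.

## Distributions and grids

A PNSD record is dN/dlog10(d_p) in cm⁻³ on a fixed grid of geometric bin
mid-diameters (SMPS-export convention), by default 8–1000 nm at 16 bins
per decade (34 bins). All integrals are midpoint sums
Σ dN/dlog10(d_p)·Δlog10(d_p); band membership is half-open on the bin
midpoint, [d_low, d_high). This makes band partitions exactly additive
and keeps mass, number and condensation-sink integrals on identical
positional grids. Grids read from CSV headers infer bin widths from the
central log10 spacing of the midpoints.

Whether fitting should be done in dN/dlogd_p or dN/dd_p space is an open
choice for this kind of data; everything here works in dN/dlog10(d_p)
space, which is both the instrument-export convention and the space in
which a lognormal mode is Gaussian.

## Multi-lognormal decomposition

A mode is (N, gmd, gsd); in log10-diameter space it contributes
N/(√(2π)·log10 gsd)·exp(−(log10 d − log10 gmd)²/(2 log10² gsd)), so the
log-diameter integral of one mode is exactly N. `MultiLognormalModel`
fits 1..max_modes modes by bounded least squares
(`scipy.optimize.least_squares`, trf) on log10(dN/dlogd_p + ε) with
ε = 0.1 cm⁻³; the log-space objective stabilises the low tails, and the
floor keeps empty bins finite. Parameters are optimised as log10(N),
log10(gmd), log10(log10 gsd) with bounds N ∈ [10⁻³, 10⁷] cm⁻³,
gsd ∈ [1.05, 3.2], and gmd allowed half a decade past either grid edge
(truncated modes are real: the instrument cutoff at 8 nm clips fresh
nucleation modes). Starts come from local maxima of a Savitzky–Golay
smoothed log-distribution, padded with number-quantile positions; three
seeded jittered restarts guard against bad starts. The mode count is
chosen by BIC computed on the log-space RSS, with the RSS floored at a
relative scale (10⁻¹² per point) so an exact fit cannot reward extra
modes. Modes are returned sorted by ascending gmd.

## Condensation sink

CS = 4πD ∫ β_m(d_p)·d_p·n(d_p) dd_p with D the diffusion coefficient of
the condensing vapor and β_m the transition-regime correction

    β_m(Kn) = (1 + Kn) / (1 + 1.677·Kn + 1.333·Kn²),  Kn = 2λ/d_p.

Under this definition Kn ≫ 1 is the free-molecular regime (small
particles, per-particle integrand ∝ d_p²) and Kn ≪ 1 the continuum
regime (large particles, ∝ d_p); the tests check both asymptotes
numerically. Vapor defaults are sulfuric-acid-like: D = 8.0×10⁻⁶ m² s⁻¹,
M = 0.098 kg mol⁻¹, T = 293.15 K, λ = 3D/c̄ with c̄ = √(8RT/πM)
(≈ 95 nm), sticking coefficient 1; all overridable. The banded sinks
partition 8/20/40/100/200/900 nm (nucleation, Aitken, soot, condensation,
larger accumulation); band edges are configurable (a 200–800 nm upper
band is a supported variant). Discretised CS agrees with fine quadrature
of the same integrand within 2% at 16 bins/decade for smooth
distributions.

## PM₁ mass and eBC

PM₁ is the volume integral of the PNSD under spherical particles with a
size-dependent density. Only the density range 1.25–1.5 g cm⁻³ is
physically anchored; the shape is a design choice here: ρ(d_p) linear in
log10(d_p) from 1.25 at 8 nm to 1.5 at 1000 nm (smooth, monotone,
endpoints honoured), overridable, with constant density as a degenerate
case. Equivalent black carbon converts 880-nm absorption with
MAC = 7.77 m² g⁻¹ (the aethalometer manufacturer convention), also
configurable.

## Daily aggregation

Exposure days run 08:00→08:00 local wall-clock (no DST handling —
campaign-scale tool). Daily values are arithmetic means; coverage is the
record count divided by the count expected at the series' median
cadence, and windows under 75% coverage (configurable) are flagged but
still reported.

## Aerosol typing

Records × bins matrices are transformed log10(x+1) then per-bin
standardised (default; `log10` and `none` are provided because the
preprocessing of published PCA analyses of this kind is rarely stated).
PCA uses the full SVD with the sign fixed so each component's
largest-magnitude loading is positive. Clustering is seeded k-means with
20 restarts, k chosen by mean silhouette over 2..6 — the standard
workhorse pair for PNSD categorisation; both are config-exposed rather
than claimed canonical. Cluster means are computed on the original
concentration scale and decomposed with the multi-lognormal model.

Archetype labels are rule-based on the fitted modes: traffic_nucleation
(smallest gmd < 20 nm, accumulation (>100 nm) number share < 10%),
urban_aged (accumulation share > 40%, or BC-to-OA below the 0.25
freshness threshold when supplied), regional_npf (smallest gmd < 20 nm
with occurrence concentrated near midday and decoupled from rush hours),
otherwise urban_fresh; unclassifiable means fall out as `unclassified`.
A known limitation: NPF modes that grow through the afternoon smear the
cluster mean above the 20 nm rule threshold, so slowly-growing NPF
clusters can land in `urban_fresh`; the traffic cluster, identified by
weekday rush-hour occupancy, is robust to this.

## ALI deposition dose

Per-bin deposition velocity is a documented three-term model:
Stokes settling with Cunningham slip (slip constants 1.257/0.4/1.1, air
mean free path scaled from 67.3 nm at 296.15 K / 101325 Pa, Sutherland
viscosity), Sherwood-type diffusive deposition v = Sh·D_B/h (Sh default
2, D_B Stokes–Einstein), and a Stokes-number impaction efficiency
Stk²/(Stk² + Stk_crit²) on the face velocity with Stk_crit = 0.25.
Chamber defaults (1.13 cm² insert, 30 cm³ min⁻¹, 0.2 cm gap, 37 °C) are
placeholders recorded in provenance — commercial exposure modules do not
publish these coefficients.

Limitation, stated plainly: a passive model of this kind deposits only
~10⁻³–10⁻² of the delivered submicron mass at such flows, i.e. of order
0.1–1 ng cm⁻² for a 24-h exposure at PM₁ ≈ 5 µg m⁻³. Reported ambient
ALI doses of hundreds of ng cm⁻² sit on the scale of the *delivered*
mass (C·Q·t/A ≈ 190 ng cm⁻² under the defaults above), which is why
`DoseResult` reports both `mass_dose_ng_cm2` (deposited) and
`delivered_mass_ng_cm2` (upper bound), plus their ratio as a deposition
efficiency. Matching a specific module's measured efficiency requires
calibrating the exposed coefficients against that module.

## Exposure–response layer

Fold changes follow the 2^−ΔΔCt convention; replicate (e.g. triplicate)
Ct arrays aggregate as the geometric mean of replicate fold changes with
the sd of those fold changes, dropping and flagging incomplete
replicates. OP and ROS mass-normalisations are plain ratios to PM₁ with
zero-mass days flagged NaN.

The correlation layer reports pairwise-complete Pearson R² and Spearman
ρ² (mid-rank ties) with two-sided p-values and per-pair n; no
multiple-testing correction is applied by default (matching how such
matrices are conventionally reported), with Benjamini–Hochberg available
as an explicit option.

`OPCSModel` is OLS of an endpoint on z-scored predictors (total DTTv
plus any chosen CS bands) with intercept, via statsmodels;
standardisation makes coefficient signs and magnitudes comparable.
Condition numbers above 30 trigger a collinearity warning with VIFs. A
permutation null (response permuted against predictors) is provided for
an honest significance check at campaign n.

`SegmentedResponseModel` fits a continuous two-piece line
y = b₀ + s₁x + (s₂−s₁)·max(0, x−ψ), grid-searching ψ over [5, 40] µg m⁻³
in 1 µg m⁻³ steps (≥3 points required on each side; otherwise a flagged
linear fallback) and comparing against a single line by BIC, counting
the breakpoint as a parameter. Continuity at the breakpoint is the
conservative choice for smooth concentration–response data. The RSS is
floored at a relative scale so exactly-linear input prefers the linear
model.

## Synthetic campaigns

The generator is first-class, tested code: it defines the conditions
every downstream test and the acceptance script run under. Three
archetypes (urban_fresh, urban_aged, regional_npf) are parameterised by
scheduled lognormal modes (hour-of-week multipliers), covariate
couplings and response coefficients; the packaged 16-day campaign is
four 4-day Tuesday→Saturday blocks (fresh / aged-with-amplitude-ramp /
fresh / NPF) at 10-min cadence from a Tuesday 08:00.

Key calibration constants (invented, config values, never measurements):
urban_fresh modes 8000 cm⁻³ @ 18 nm (gsd 1.6, rush-hour schedule),
1500 @ 48 nm, 250 @ 150 nm background, BC-to-OA 0.35; urban_aged
800 @ 250 nm + 1200 @ 70 nm, BC-to-OA 0.10, day amplitudes 0.3–2.3
emulating stagnation buildup; regional_npf 6000 @ 18 nm midday with 15%
gmd growth per hour from 10:00 plus a 400 @ 200 nm background, BC-to-OA
0.15. These land daily PM₁ at roughly 1.6–60 µg m⁻³ across the campaign
and make intrinsic OP (DTTm) highest on fresh nucleation days. PNSD bin
noise is multiplicative lognormal with sd 0.10; daily
DTTv = 0.05·Cu + 4×10⁻⁴·N₈₋₂₀ + 0.02·PM₁ (fresh/aged; weaker couplings
for NPF) with lognormal sd 0.08. Gene responses are
fc = max(0.05, 1 + a·z(DTTv) + b·z(CS₈₋₂₀) − c·z(CS₂₀₀₋₉₀₀) + ε) with
(a, b, c) = (0.45, 0.15, 0.35) for HMOX-1 and (0.55, 0.20, 0.40) for
CXCL-8, ε ~ N(0, 0.12), reported as geometric means of simulated
triplicates with sd and a two-sided one-sample t-test p-value on the log
replicates.

Randomness derives from one seed through `numpy.random.SeedSequence`
sub-streams (PNSD / covariates / reference / response), so regenerating
with the same seed is byte-identical and perturbing, say, response noise
cannot move the aerosol fields.

What the generator does **not** emulate: meteorology and transport,
instrument inversion artifacts (multiple charging, diffusion losses),
autocorrelated measurement error, covariate confounding beyond the
stated couplings, non-linear or threshold biology, and day-to-day
biological variability of the cell model. Passing tests therefore
demonstrate that the estimators recover the structure they assume when
that structure is present at realistic noise — not that real campaigns
satisfy those assumptions.

## Problem sizes used in the packaged checks

The packaged campaign is 16 days × 144 records × 34 bins (2304 records).
Monte-Carlo checks use 50 replicate two-mode fits and 100 single-mode
fits (5% bin noise), 200 response-replicate sign-recovery fits, 200
segmented-fit replicates at n = 16 days, and 1000 independent-noise
simulations for the 5% type-I calibration of the correlation layer —
sizes at which the medians and rates under test are stable to well
inside their asserted tolerances.
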