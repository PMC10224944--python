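# Methods

## The isotope mass balance

Soil organic nitrogen integrates the isotopic fractionation of the
pathways by which nitrogen leaves an ecosystem.  Denitrification
discriminates strongly against ¹⁵N (ε_denit ≈ 10–20‰ in natural soil
communities), hydrological leaching hardly at all (ε_leach ≈ 0), and NH₃
volatilization very strongly (ε_vol ≈ 29–35‰) but is a minor flux in
natural systems.  At steady state (losses balancing inputs) the soil
signature is

    δ¹⁵N_soil = δ¹⁵N_input + f_denit·ε_denit + f_leach·ε_leach + f_vol·ε_vol,

with f_denit + f_leach + f_vol = 1.  Given a soil δ¹⁵N map and the
flux-weighted input signature

    δ¹⁵N_input = (I_dep·δ_dep + I_bnf·δ_bnf + I_rock·δ_rock) / (I_dep + I_bnf + I_rock),

the denitrified fraction of N loss inverts to

    f_denit = (δ¹⁵N_soil − δ¹⁵N_input − f_vol·ε_vol − (1 − f_vol)·ε_leach)
              / (ε_denit − ε_leach).

`forward_delta` and `invert_fdenit` are exact inverses of one another over
the whole admissible parameter space (a property test holds this to
1e-12).  Values are clipped to the physical range [0, 1 − f_vol]; the
clipped cell fraction is reported rather than hidden, since clipping marks
cells where the observed δ¹⁵N is inconsistent with the assumed inputs.

### Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| ε_denit | 13 | ‰ | lower end of the 10–20‰ natural-soil range, giving a conservative (high) f_denit |
| ε_leach | 0 | ‰ | leaching fractionation is negligible |
| ε_vol | 29 | ‰ | lower end of the 29–35‰ volatilization range; inactive while f_vol = 0 |
| f_vol | 0 | – | NH₃ volatilization is <5% of natural N loss and absent from most model output; the mechanism stays available |
| SD(ε_denit) | 1.02 | ‰ | uncertainty kept within ±2 SD ≈ 4‰ |
| SD(ε_leach) | 0.51 | ‰ | uncertainty kept within ±2 SD ≈ 2‰ |
| SD(δ¹⁵N_input) | 5% of \|mean\| | – | relative input-signature uncertainty; the absolute value is used because the mean input signature is typically negative |

Monte Carlo propagation (`monte_carlo_fdenit`) samples all of these as
Gaussians per cell and draw, inverts each draw, and clips **per draw**
(keeping every draw physical) before averaging.  Draws violating
ε_denit > ε_leach are redrawn rather than truncated, preserving the
distribution away from the constraint; more than 10% redraws aborts.
With only ε_denit uncertain the MC SD matches the first-order
delta-method value (δ_soil − δ_input)·σ_ε/ε² — the calibration test runs
at 10⁵ draws with a 15% band, wide enough for the second-order curvature
of 1/ε.

The ε_denit sensitivity mechanism supports both a fixed-value sweep
(10–20‰) and a linear temperature dependence ε(T) = a + b·T with
user-supplied coefficients.

## Site filtering and aggregation

Only natural mineral topsoil (≤30 cm) carries the steady-state loss
signal, so records are excluded by eight rules, evaluated in order a–h
with multi-rule violators counted once under the first match: (a) sample
bottom deeper than 30 cm, (b) C:N < 1 gC gN⁻¹, (c) N concentration
< 0.02 mg g⁻¹, (d) organic-horizon-only sample or C concentration
> 610 mg g⁻¹, (e) litter layer, (f) coastal/marine-adjacent site,
(g) cropland, (h) pasture/drystock/dairy/industrial.  Decisions the rule
text leaves open, fixed here: the depth rule tests the layer bottom
(records straddling 30 cm are excluded, not truncated); rule (d) is a
single OR-rule; missing metadata never excludes a record (conservative
keep).

Multi-depth sites are collapsed by an N-content-weighted mean,
Σ(δᵢ·Nᵢ)/Σ(Nᵢ), with per-layer N content approximated as concentration ×
layer thickness; when either is missing, layers weight equally.
Aggregation to grid cells is an unweighted mean per cell; cells are
half-open [edge, edge) intervals with the maximum edge folded into the
last cell, so every in-extent site belongs to exactly one cell.

## Upscaling

A random forest (default 500 trees, unlimited depth, √p features per
split, seeded) regresses cell-mean δ¹⁵N on 16 predictors: climate (P, T,
P/PET), soil properties (BD, pH, clay, silt, sand, OC, C:N), microbial
symbionts (AM, ECM, Nfix), GPP, and NHₓ/NOᵧ deposition.  The
hyperparameters are declared defaults chosen for variance stability, not
tuned.  Evaluation: R² = 1 − SSE/SST and RMSE on a seeded 80/20 hold-out
split, plus K-fold (default K=10) cross-validation with folds drawn from
a seeded shuffle (so results are invariant to row order).  Prediction
uncertainty is the across-tree SD.  Feature importance is permutation
importance on held-out rows — comparable across feature scales, unlike
impurity importance.  A climate-only OLS baseline (δ¹⁵N ~ T + P) is the
comparison model; on nonlinear synthetic truth the forest's hold-out R²
exceeds the baseline's, which is the methodological reason to upscale
with a forest at all.

## Budgets

Global means are weighted by N-input flux × spherical cell area (at
steady state soil N content is proportional to N input).  Cell areas use
the exact spherical formula R²·Δλ·(sinφ₂ − sinφ₁); any consistent area
model preserves the tested identities, e.g. steady_state_denit(f, I) =
weighted_mean(f, I) × total_input.  Latitudinal gradients are OLS slopes
of area-weighted zonal means on 1° bands of |latitude|, reported per 10°
(a signed-latitude variant is available).  ESM-style closure back-computes
the model's N input as sink + losses, with the sink as the mean annual
increment of the land N stock.  Reported bias percentages are rounded
half-up to integers.

## CO₂ sensitivity (β_NPP)

In historical simulations T, P and CO₂ trend together, so the regression
is staged: (1) OLS of detrended NPP on detrended T and P gives the
climate sensitivities α_T, α_P; (2) the residual NPP − α_T·T − α_P·P −
α_const, computed on the **raw** series exactly as the two-equation
procedure specifies (the CO₂-driven trend must survive into the
residual), is regressed on CO₂.  β_NPP is reported as percent of
period-mean NPP per ppm (the normalization is configurable; first-decade
mean is a reasonable alternative).  Regional series are area-weighted
aggregates over the boreal band before regression.

Two estimator properties discovered while validating on synthetic bundles
are worth recording.  First, when the CO₂ trajectory is exactly linear in
time, CO₂ lies in the span of the linear detrending basis and the
two-stage estimate is *algebraically identical* to the CO₂ coefficient of
a joint OLS of NPP on (T, P, CO₂); the procedures only differ under a
curved CO₂ ramp.  The two-stage form remains preferable because it stays
well-conditioned as the trends become collinear, and it is unbiased in
that regime (both are asserted as tests).  Second, the naive OLS standard
error of the second stage understates the true uncertainty: the
first-stage error in each α multiplies that regressor's CO₂-trend
component and leaks into the residual slope.  `beta_pipeline` therefore
inflates the slope SE by (SE(α_T)·dT/dCO₂)² + (SE(α_P)·dP/dCO₂)² added in
quadrature.  Without this the empirical 95% CI coverage on synthetic
bundles was ≈90%; with it, coverage is nominal (38/40 seeded worlds).

The cross-model regression of β_NPP on f_denit is standard OLS with a
two-sided slope t-test (n−2 df) and a 95% CI band on the regression mean.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

- **Smooth surfaces** are mixes of ~10 low-frequency harmonics with random
  integer wavenumbers (0–3 per axis), normalized to unit SD — adequate
  spatial autocorrelation at negligible cost; they are not
  Gaussian-process samples and have no tunable correlation length.
- **True f_denit** declines linearly with |latitude| from 0.7 (tropics) to
  0.15 (boreal) plus smooth noise (SD 0.03), clipped to [0, 1] — an open
  tropical N cycle, a closed boreal one.
- **Soil δ¹⁵N truth** is the *exact* forward balance of the true f_denit;
  noise (default 1.5‰, a test convenience, not a claim about real
  site-to-cell scatter) enters only when observations or site records are
  sampled.
- **N-input sets** enumerate the six rock × deposition × fixation
  combinations: rock 10 Tg N yr⁻¹ at ~4.02‰ (lithology signature bounded
  by 1.47–6.57‰), deposition 39 or 42 Tg at 0‰, fixation 46, 44 or 81 Tg
  at −2‰.  Ensemble totals average ~107 Tg N yr⁻¹ with SD ~18; the
  flux-weighted input signature per set falls in −1.1…−0.3‰.  Fixation is
  tropics-weighted; every flux map is rescaled so its spherical area
  integral matches the component total exactly.  Beyond six sets the
  totals receive a 5% lognormal jitter.
- **ESM bundles** prescribe a model f_denit on a smooth total-loss field
  (near-saturated uniform 0.9 by default), a land-N-stock series with a
  prescribed sink (25 Tg N yr⁻¹), and boreal regional series with
  NPP = 400·(1 + β·ΔCO₂) + 10·T + 0.1·P + noise (g C m⁻² yr⁻¹ scale,
  β = 0.0015 ppm⁻¹ ≈ 0.15% ppm⁻¹), T trending +0.02 °C yr⁻¹ with 0.7 °C
  interannual noise, P trending +0.5 mm yr⁻¹ with 40 mm noise, NPP noise
  1% of baseline, and a CO₂ ramp rising exactly 81 ppm over 1960–2014
  (linear by default, convex optional).
- All generators are bit-deterministic for a fixed seed (independent
  `SeedSequence` streams per generator), and injected quality-rule
  violations carry a hidden site-id → rule label for tests only.

What passing the recovery tests does *not* show: the generator has no
ocean mask, no real covariance between predictors and δ¹⁵N beyond shared
latitudinal structure, no sampling bias toward accessible regions, no
inter-dataset heterogeneity, and ESM families' actual near-binary f_denit
histograms are only mimicked by a configurable uniform level.  Recovery
within ±0.05 on this world demonstrates that the pipeline is consistent —
not that real-data uncertainty is this small.

## Problem sizes

Default test grids are 10° (unit tests) and 2° with 3000 sites
(end-to-end recovery); the 0.1° convention of the global analysis is
supported by the same code paths.  Monte Carlo calibration uses 10⁵ draws
on a single cell; CI coverage uses 20 seeded worlds of 55 years.  These
sizes were chosen so the full suite completes in well under a minute of
compute per heavy test while keeping every statistical check comfortably
above its noise floor.

## Known limitations

- Steady state is assumed where the balance is inverted; the sink-bias
  bound (≈1% of f_denit) is arithmetic on supplied Δf, not a derivation
  of Δδ¹⁵N from sink fluxes.
- Gaseous loss is not partitioned into N₂O/NO/N₂.
- The NetCDF interface writes NETCDF3_CLASSIC.
- `fit_beta` alone reports the plain OLS SE; only `beta_pipeline` adds the
  first-stage propagation term.
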