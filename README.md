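# isodenit

Isotope mass-balance benchmarking of terrestrial denitrification nitrogen
loss — for biogeochemists who want to partition ecosystem N losses between
denitrification and leaching from natural-abundance soil δ¹⁵N, and to
evaluate the N-loss pathways simulated by Earth System Models against that
benchmark.

## The science

Denitrification discriminates strongly against ¹⁵N (ε_denit ≈ 13‰ in
natural soils), leaching hardly at all, so the soil δ¹⁵N signal records
how much of an ecosystem's N loss left as gas.  At steady state

    δ¹⁵N_soil = δ¹⁵N_input + f_denit·ε_denit + f_leach·ε_leach + f_vol·ε_vol

with f_denit + f_leach + f_vol = 1, which inverts (ignoring the minor
volatilization term) to

    f_denit = (δ¹⁵N_soil − δ¹⁵N_input − ε_leach) / (ε_denit − ε_leach)

where δ¹⁵N_input is the flux-weighted mean signature of atmospheric
deposition (~0‰), biological N fixation (~−2‰) and rock N weathering
(~4‰).  The package implements the full workflow around this inversion:

- **`sites`** — quality-filter raw soil δ¹⁵N records (eight exclusion
  rules: depth, C:N, N and C concentration, horizon, coastal, managed
  land), depth-average by N content, aggregate to grid cells;
- **`upscaling`** — random-forest regression of cell-mean δ¹⁵N on 16
  environmental predictors, with hold-out/K-fold evaluation, permutation
  importance, and a climate-only linear baseline;
- **`isotope`** — input-signature mixing, the forward balance and its
  exact inverse, Monte Carlo uncertainty propagation, input-set ensembles,
  ε sensitivity scenarios;
- **`budget`** — N-input-weighted global means, steady-state
  denitrification budgets, ESM f_denit, budget closure
  (input = sink + losses), loss reallocation, bias percentages,
  latitudinal gradients, histograms, managed-land masking;
- **`co2`** — the two-stage detrended-residual regression for β_NPP (the
  sensitivity of NPP to CO₂, % ppm⁻¹) and the across-model regression of
  β_NPP on f_denit;
- **`synthetic`** — seeded generators for every input the workflow needs,
  with recorded ground truth for parameter-recovery testing.

See `docs/methods.md` for the model, parameter defaults and design
decisions.

## Worked example

```python
from isodenit import (GridSpec, ensemble_fdenit, weighted_global_mean,
                      steady_state_denit, global_total_tg)
from isodenit.budget import close_budget, latitudinal_gradient, overestimation_percent
from isodenit.co2 import beta_pipeline
from isodenit import synthetic

spec = GridSpec(resolution=4.0)
truth, input_sets, params = synthetic.make_synthetic_world(spec, seed=42)
obs = synthetic.make_soil_delta_obs(truth, input_sets[0], params, noise_sd=1.5, seed=42)

fdenit, spread, _ = ensemble_fdenit(input_sets, obs, params)
w = input_sets[0].total_flux
print(f"global N-input-weighted f_denit: {weighted_global_mean(fdenit, w):.3f}")
print(f"true value:                      {weighted_global_mean(truth.true_fdenit, w):.3f}")
print(f"latitudinal gradient:            {latitudinal_gradient(fdenit):+.3f} per 10 deg")
print(f"steady-state denitrification:    {steady_state_denit(fdenit, w):.1f} Tg N/yr")

bundle = synthetic.make_esm_bundle(truth, spec, model_fdenit=0.9, seed=42)
summary = close_budget(bundle)
bench = weighted_global_mean(fdenit, bundle.denit_flux + bundle.leach_flux)
print(f"f_denit bias: model {summary.fdenit_weighted_mean:.2f} vs benchmark {bench:.2f}"
      f" -> {overestimation_percent(summary.fdenit_weighted_mean, bench)}% overestimate")
est = beta_pipeline(bundle)
print(f"beta_NPP: {est.beta_pct:.3f} % per ppm (true {bundle.truth['true_beta_pct']:.3f})")
```

prints

```
global N-input-weighted f_denit: 0.522
true value:                      0.523
latitudinal gradient:            -0.060 per 10 deg
steady-state denitrification:    49.6 Tg N/yr
f_denit bias: model 0.90 vs benchmark 0.51 -> 78% overestimate
beta_NPP: 0.139 % per ppm (true 0.136)
```

The ensemble inversion recovers the prescribed global denitrification
fraction to three decimals on this noisy 4° world; the ESM-style bundle
with near-saturated denitrification (f_denit = 0.9 everywhere) is flagged
as a 78% overestimate against the isotope benchmark; and the two-stage
regression recovers the prescribed CO₂ sensitivity of plant production.

A CLI mirrors the workflow for file-based use:

```sh
isodenit simulate --seed 3 --resolution 2 --n-sites 1000 --out-dir sim
isodenit filter --in sim/sites.csv --out kept.csv --report report.txt
isodenit fdenit --soil sim/delta15n.nc --inputs sim/ninput_set1.nc --out fdenit.nc
```

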