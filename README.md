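# deprivmap

Bayesian small-area deprivation ("slum") mapping for census enumeration areas
(EAs), end to end:

1. **synthetic_data** — contiguous EA lattices grouped into neighbourhoods,
   household microdata driven by a latent deprivation score, smooth DEM/NDVI
   raster fields, and binary deprived labels drawn from the exact logistic
   generative model `logit(p_ij) = alpha + beta.x_ij + V_j`.
2. **predictors** — the 18-column EA predictor matrix: household category
   proportions per variable group (water, toilet, tenure, wall, roof, floor,
   fuel, rubbish, dwelling), crowding (mean persons per bedroom), population
   density, zonal NDVI mean, and the EA-minus-5-km-buffer elevation
   difference, with an optional recorded standardization transform.
3. **model** — Bayesian logistic regression by MCMC (coordinate-wise slice
   sampling) with Normal(0, 0.98²), lasso (double-exponential) or ridge
   (normal with inverse-gamma precision) coefficient priors, optional
   neighbourhood random intercepts with a half-Cauchy SD prior, split R-hat /
   ESS diagnostics, and odds-ratio summaries.
4. **selection** — hold-out cross-validation at fractions 2.5–10% with MSE
   (Brier or fitted-probability reference), and WAIC.
5. **predict** — posterior-predictive probabilities for urban EAs, 95%
   credible intervals, quintile bins with EA/population shares, the ≥0.80
   deprived threshold, and contiguous clusters of ≥3 deprived EAs.
6. **lisa** — global and local Moran's I on queen-contiguity
   row-standardized weights with conditional-permutation pseudo p-values and
   HH/LL/HL/LH classing.
7. **cli** — a YAML-configured pipeline with a deterministic run manifest.

All file formats are plain text: GeoJSON for EA polygons and map outputs,
CSV for tables, ESRI ASCII grid (`.asc`) for rasters.

## CLI

Every command takes a YAML config (see `fixtures/demo/config.yaml` for a
complete example):

```sh
deprivmap simulate         --config cfg.yaml --out run/   # synthetic inputs
deprivmap build-predictors --config cfg.yaml --out run/
deprivmap fit              --config cfg.yaml --out run/
deprivmap select           --config cfg.yaml --out run/
deprivmap predict          --config cfg.yaml --out run/
deprivmap lisa             --config cfg.yaml --out run/ --variable toilet_public
deprivmap run              --config cfg.yaml --out run/   # all of the above
```

`run` writes `manifest.json` with a sha256 per artifact; rerunning the same
config reproduces identical hashes. The committed `fixtures/demo/` bundle
(100 EAs, 4 neighbourhoods) is regenerated byte-identically by
`deprivmap fixture`.

## Library example

```python
from deprivmap import model, predict, selection, synthetic_data as sd

bundle = sd.generate_bundle(sd.SyntheticConfig(n_neighbourhoods=9,
                                               eas_per_neighbourhood=36,
                                               seed=1))
spec = model.ModelSpec(n_iter=2000, burn_in=500, n_chains=2, seed=2)
draws = model.fit(spec, bundle["X"], bundle["labels"].y)
print(model.summarize_or(draws).head())
print(selection.waic(draws.pointwise_loglik))
pred = predict.posterior_predict(draws, bundle["X"], frame=bundle["frame"])
print(predict.quintile_table(pred, bundle["frame"]))
```
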