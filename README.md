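# phenokrig

Geostatistical analysis of flowering phenology for sparse monitoring
networks, built around the spring flowering of the grass *Vulpia geniculata*
in and around Córdoba (SW Spain): ten sites scored weekly on a 0–4
phenophase scale are enough, with the right spatial statistics, to map the
flowering state of a whole ~17 × 10 km study area and relate it to the
airborne pollen curve recorded by a volumetric trap.

The package is aimed at aerobiologists and spatial ecologists who have a
handful of georeferenced phenology observations per date and want validated
interpolated maps rather than per-site time series.

## The method

For each survey date with phase values `z(x_i)` at sites `x_i`:

1. **Screening** — mean `m`, sample variance, extrema and coefficient of
   variation per date; values outside `m ± 3s` are flagged as outliers.
2. **Structural analysis** — the empirical semivariogram
   `γ̂(h) = Σ (z_i − z_j)² / 2N(h)` over distance-binned point pairs, fitted
   with an isotropic Gaussian model
   `γ(h) = C0 + C·(1 − exp(−(h/A0)²))`
   (nugget `C0`, sill `C0 + C`, effective range `√3·A0`) by bounded least
   squares, reporting `r²` and the residual sum of squares.
3. **Simple kriging** — predictions
   `Z*(v) = Σ λ_i Z(x_i) + m(1 − Σ λ_i)` with weights from the covariance
   system `Cλ = c`, `Cov(h) = (C0 + C) − γ(h)`, evaluated at every cell of a
   regular grid over the study area.
4. **Leave-one-out cross-validation** — each site is removed in turn and
   re-predicted from the others; the OLS regression of actual on estimated
   (slope ≈ 1 for a good model) plus RMSE score the interpolation.
5. **Mapping and pollen comparison** — cells with phase between 1.5 and 2.5
   are classified as populations at full flowering (maximum pollen release);
   the full-flowering area fraction per date is joined against the weekly
   airborne-pollen index (daily grains/m³ summed over 7-day windows).

The raw per-point values of the original campaign were never published, so
the package ships a synthetic survey generator with the same statistical
structure (spatially autocorrelated phase fields advancing weekly, delayed
with altitude, observed as clamped 5-quadrat means) plus the published
summary tables as reference fixtures.

## Worked example

```python
from phenokrig import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(seed=42, outdir="demo", cellsize=250.0))
print(manifest["peak_week"])
```

```
{'week_start': '2004-05-03', 'index': 1594.1601877945893, 'tied': False}
```

The run simulates a 10-site survey over six weekly dates, then writes one
kriged raster (`pheno_<date>.asc`), one descriptive/outlier row, one
variogram fit and one cross-validation row per date into `demo/`, plus the
weekly pollen join and a checksummed `manifest.json`. Key outputs
(`demo/area_fractions.csv`, rounded):

```
      date  area_fraction  altitude_phase_rho
2004-04-23          0.000              -0.515
2004-04-30          0.572              -0.309
2004-05-07          0.952              -0.782
2004-05-14          0.103              -0.576
2004-05-21          0.084              -0.721
2004-05-28          0.003              -0.571
```

The full-flowering fraction peaks on 7 May — the same week the simulated
pollen index peaks (week starting 3 May, above) — and the consistently
negative altitude–phase rank correlation shows lower sites flowering ahead
of the Sierra, the spatial pattern the mapping stage is designed to expose.
`demo/describe.csv` carries the per-date screen (no outliers here), and
`demo/cv.csv` the per-date cross-validation slopes, which at n = 10 sites
are as scattered as sparse-network cross-validation typically is.

The same workflow is available from the shell:

```bash
phenokrig run-all --seed 42 --outdir demo
phenokrig simulate --seed 1 --outdir sim
phenokrig describe sim/points.csv sim/observations.csv
phenokrig variogram cordoba obs.csv   # 'cordoba' = the study's 10 real sites
```

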