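# Methods

## Data model

A survey is a set of georeferenced sites (projected easting/northing in
metres, altitude in m a.s.l., bioclimatic belt) each carrying, per weekly
date, a phenophase value on [0, 4]: the mean of five 1 m² quadrat scores on
the 0–4 flowering scale (0 pre-flowering, 1 ≤25 % flowers open, 2 25–75 %,
3 >75 % with anthers emptying, 4 past flowering). Although quadrat scores
are integers, recorded site means such as 1.75 are not multiples of 1/5, so
the data model accepts any real on [0, 4]. Stage boundaries at exactly 25 %
or 75 % open flowers are assigned to the lower stage; the definitions are
approximate percentages and the tie-break must simply be fixed.

Coordinates are treated as planar and distances as Euclidean. At a study
extent of ~17 km the difference from geodesic distance is far below the lag
resolution of any variogram built from ≤45 point pairs, so no geodesy or
reprojection is performed; the ESRI ASCII grid writer likewise records bare
planar coordinates.

## Outlier screen

Per date: mean, sample variance (n−1 denominator; with n ≤ 10 the choice is
immaterial for screening but the sample convention is standard), extrema,
coefficient of variation s/m (undefined and flagged at m = 0), and the
thresholds m ± 3s. Values strictly outside the band are outliers; boundary
values are kept. Of the 34 threshold cells printed in the original
campaign's summary tables, 13 are exactly reproducible at 2 dp from the
printed mean and variance of their column; the remainder differ by
0.01–0.02 because they were evidently computed from unrounded statistics.
The reproducible cells are the package's arithmetic reference surface.

## Variography

The empirical semivariogram is the method-of-moments estimator over uniform
lag bins on (0, max_lag]; a pair at distance d enters bin ⌈d/w⌉ with
w = max_lag/n_lags, empty bins are dropped, and each bin reports its mean
pair distance. Defaults: n_lags = 6 and max_lag = the maximum pairwise
distance, so that a 10-site network (45 pairs) keeps every pair; both are
configurable.

Phenophase fields are very smooth in space, so the Gaussian model
γ(h) = C0 + C(1 − exp(−(h/A0)²)) is the default (spherical and exponential
are available). The parameterisation follows the desktop-geostatistics
convention in which A0 is the range *parameter* and the effective range is
√3·A0. Fitting minimises the residual sum of squares over bins — optionally
weighted by pair count, default unweighted since a single RSS is reported —
by bounded trust-region least squares (C0 ≥ 0, C ≥ 0, A0 > 0) from a
deterministic start list (C0 = 0, C = max γ̂, A0 ∈ {¼, ½, 1}·max_lag; the
binned γ̂ is the data available to the fitter, so its maximum stands in for
the process variance as the sill start). The exact pure-nugget solution
(C0 = weighted mean γ̂, C = 0) is always evaluated as a candidate, which
guarantees RSS ≤ RSS(flat model) and hence r² = 1 − RSS/TSS ∈ [0, 1]. A
flat empirical variogram returns the pure-nugget model with A0 flagged
unidentifiable and r² undefined (NaN).

With trend-contaminated or erratic small-n variograms the optimiser may run
to a very large A0/C pair whose curve is nearly linear over the observed
lags; this is the correct least-squares answer on those bins and is
reported as such rather than being clipped.

## Simple kriging

The stationary mean m required by simple kriging is the dataset's
arithmetic mean by default (a median option exists). The estimator's
published description garbles m into a median-like formula mid-sentence;
the conventional stationary-mean reading is implemented and the alternative
is exposed as the documented option rather than guessed further.

Weights solve Cλ = c with Cov(h) = (C0+C) − γ(h): Cov(0) = C0 + C, so data
are treated as error-free and interpolation is exact only at C0 = 0. The
`nugget_as_error` option implements filtered kriging: the data–data matrix
keeps the nugget (observations are noisy) while the target–data covariances
drop it, predicting the noise-free signal. All ≤12 data enter every
prediction (no search neighbourhood — pointless at this n); the SPD system
is solved by dense Cholesky, factorised once per date and reused across all
grid cells. Kriging variance (C0+C) − λᵀc is clipped to 0 below −1e-10
with a warning. Grid estimates are clamped into [0, 4] only at the map
stage, with per-cell clamp flags; point predictions are returned unclamped.

Default grid: the data bounding box padded 5 % per side, 100 m cells
(~170 × 100 cells for the study extent, fractions of a second with the
vectorised solve).

## Cross-validation

Leave-one-out: each site is predicted from the other n−1 with the variogram
held fixed (refitting on 6 points is unstable; a `refit_per_fold` flag
exists) and the mean recomputed from the retained values. Quality is the
OLS regression of actual on estimated — the geostatistical convention for
cross-validation scatter, consistent with published coefficients exceeding
1 — plus r², RMSE and bias. Constant estimates make the slope undefined;
this is returned as a flagged degenerate result, not an exception.

## Maps and pollen

Full flowering is the inclusive band 1.5 ≤ phase ≤ 2.5; the area fraction
is computed over valid cells. Class maps round half-up to the nearest
integer stage. The altitude gradient summary is the Spearman correlation
between site altitude and the kriged value at each site's cell (negative =
lower sites ahead). Weekly pollen indices are fixed 7-day sums anchored at
the first Monday on/before the first observation (configurable); missing
days contribute 0 and flag the week incomplete; peak-week ties resolve to
the earliest week with a tie flag.

## Synthetic surveys

The generator emulates the study conditions: 10 sites uniform over a
18 × 10.6 km box, altitude rising with northing from 90 to 590 m (±30 m
jitter), six weekly dates, latent phase
z_t(x) = β0 + r·t + β_alt·alt(x) + G(x) with β0 = 1.5, r = 0.53 phase/week
(the printed means advance from 1.04 to 3.68 over five weeks),
β_alt = −0.0015 phase/m (≈0.74 phase spread over the real altitude range),
and G a Gaussian random field with Gaussian covariance (structural sill
0.10, nugget 0.02 phase², range parameter 2000 m) realised exactly through
a Cholesky factor of the site covariance matrix (+1e-10 jitter).
Observations are means of 5 quadrat draws N(z, 0.35²), clamped to [0, 4]
after averaging, matching how field means were recorded. The implied
within-date variance (≈0.2 phase²) sits inside the printed 0.14–0.48 range.
Daily pollen is proportional (scale 300 grains/m³) to the fraction of the
latent trend surface inside the full-flowering band, interpolated between
survey dates, with multiplicative lognormal noise (σ = 0.3).

Randomness uses one root seed with deterministic per-purpose sub-streams,
so identical configurations are bit-reproducible. What the generator does
*not* emulate: between-date correlation of the residual field (dates are
conditionally independent given the trend), weather forcing, thermal-time
phenology, and trap-level pollen physics — so passing tests demonstrate
correctness of the statistical machinery under the assumed model, not
fidelity of any particular real season.

## Verification sizes and numerical conventions

Calibration checks run at sizes where the estimators are well conditioned
while keeping the default suite fast: leave-one-out calibration on 100-site
trend-free fields over 20 replicates (median slope, median bias), sill
recovery on 500-site fields over 20 replicates (median fitted sill), and
semivariogram correctness by exhaustive pair enumeration at n ≤ 12 over 200
random configurations. Kriging exactness and the pure-nugget limit are
checked to 1e-9/1e-12; the fitted-variogram self-consistency on noiseless
bins to 1e-6. The end-to-end pipeline writes only text artefacts with fixed
float formatting and a manifest of SHA-256 checksums that excludes the
output path, so runs with equal (inputs, config, seed) are byte-identical.

## Known limitations

Only isotropic variograms (no anisotropy, nesting, or ML/REML variography);
simple kriging only (no ordinary/universal/co-kriging or block kriging);
no pollen-season definition or forecasting; no cartographic rendering. The
published per-date variogram parameters and cross-validation coefficients
cannot be reproduced exactly because the underlying raw data are
unpublished — the shipped reference tables support qualitative comparison
only.
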