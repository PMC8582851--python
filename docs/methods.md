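# Methods

## The valuation model

esvpipe prices ecosystem services with the equivalent-factor method in
its Chinese-terrestrial form. A 5 × 9 table of dimensionless
equivalents E0ᵢⱼ (land types i: cropland, forestland, grassland,
water, unused; services j: food production, raw-material production,
gas/climate/hydrological regulation, waste treatment, soil
conservation, biodiversity maintenance, aesthetic landscape) is
anchored to one *standard equivalent factor* — 1/7 of the market
value of the annual grain yield of one hectare of average farmland —
and corrected regionally:

    Eᵢⱼ = α · (1/7) · (P·Q/A) · E0ᵢⱼ

with P the grain price (yuan/kg), Q the yield (kg), A the sown area
(hm²) and α a provincial correction coefficient (default 1.39).
Coefficients from different years are made comparable with a
fixed-base CPI rebase, VCᵢⱼ = Eᵢⱼ · CPI′/CPI₀. Because the grain and
CPI inputs behind the packaged 2015 coefficient table are not part of
the table itself, `correct_equivalents` and `deflate_cpi` are generic
transforms for user-supplied inputs, and the shipped CSV
(`esvpipe/data/esv_coefficients_2015.csv`, yuan·hm⁻²·yr⁻¹) is the
canonical coefficient source.

Per-cell valuation is the bilinear form ESV(c, j) = Σᵢ Aᵢ(c) · VCᵢⱼ,
with Aᵢ(c) the area of land type i in cell c. Land composition is
held as *fractions* of each 1 km cell (default cell area 100 hm²)
rather than a hard class label: a 1 km analysis cell aggregates much
finer land-cover mapping, so mixed cells are the norm. Construction
land has coefficient 0 by default — the convention of this method,
since no consensus coefficient exists for built land — and can be
overridden by supplying a table with a `construction` column.
Aggregation to service/category/region tables is exact summation of
unrounded values; report tables round at the end, so a rounded total
can differ from the sum of its rounded rows by a unit in the last
place.

## Change analysis

Temporal change is the plain percentage rate 100·(v₁−v₀)/v₀ (undefined
on a zero baseline, which raises). Spatial change is the per-cell
difference in yuan between two epochs, classified with Jenks natural
breaks: the exact Fisher–Jenks dynamic programme minimising the
within-class sum of squared deviations over contiguous partitions of
the sorted values (O(k·n²), numba-compiled; ties broken toward the
earlier split for determinism). Default k = 7 classes, pooled over
the full period; intervals are lower-open, upper-closed (a, b], so a
value lying exactly on a break belongs to the lower class. The
brute-force enumeration oracle in the test suite confirms DP
optimality on all instances with n ≤ 12, k ≤ 4.

## Driver attribution

Per-cell ESV is regressed on 15 covariates — elevation, slope,
temperature, precipitation, three soil-texture fractions, NDVI
(natural, X1–X8); economic density, population density, urbanization
level (humanistic, X9–X11); distances to urban areas, rural
settlements, main roads and rivers (location, X12–X15) — with a
bagged ensemble of regression trees. Each tree is grown on a
bootstrap resample of size n; the ≈(1−1/n)ⁿ → 36.8% of rows left out
of each resample form that tree's out-of-bag (OOB) set. sklearn's
`DecisionTreeRegressor` grows the trees; the bootstrap bookkeeping,
OOB prediction and everything downstream of it are implemented in the
package so the OOB quantities follow their definitions exactly.

*Tuning.* OOB accuracy is the pseudo-R² 1 − OOB-MSE/var(y). Stage 1
fixes ntree at the grid maximum (default grid {10, 25, 50, 100, 200,
500}) and picks the mtry (default grid 1–15) with the best OOB
accuracy; stage 2 fixes that mtry and picks the smallest ntree whose
OOB accuracy is within 0.002 of the best, trading ensemble size
against a negligible accuracy loss. Both stages reuse one fitted
forest per mtry (prefix evaluation over trees), and everything is
deterministic given the config seed.

*Importance.* Per-tree OOB permutation importance (mean increase in
that tree's OOB MSE when one predictor's OOB column is shuffled),
averaged over trees; negative raw values are clipped to 0 and the
vector normalised to sum 1, giving *influence coefficients* that are
shares of explained influence. Group sums over the natural /
humanistic / location factors therefore partition the unit. Grades:
level 1 > 0.3, level 2 (0.15, 0.3], level 3 (0.05, 0.15], level 4
(0.01, 0.05], level 5 ≤ 0.01 — lower level, stronger influence.
Normalisation precedes grading.

*Baseline.* `mlr_baseline` fits OLS on the same observations and
reports R² and %RMSE = 100·RMSE/mean(y) for both models (accuracy =
100 − %RMSE). The linear model is scored in-sample (its fitted values
are the simulated ESV); the forest is scored on OOB predictions so
its advantage is not a resubstitution artifact. A rank-deficient
design falls back to the pseudo-inverse and is flagged.

## Gradient differentiation

Seven drivers carry built-in gradient schemes: slope (≤2°, 2–6°,
6–15°, 15–25°, >25°) and elevation (≤200 m, 200–500 m, >500 m) from
the Chinese land-survey regulations; NDVI in equidistant fifths;
precipitation (≤500, 500–800, 800–1000, >1000 mm); population density
and economic density in decade classes; settlement distance (≤10,
10–500, 500–1000, 1000–5000, >5000 m). The economic-density unit
(yuan/km²) and the 10 m settlement bin follow the published scheme
verbatim even though they look like scale slips; both are overridable
by passing a custom `GradientScheme`. Binning uses the same (a, b]
convention as the change classes; schemes with declared hard limits
report out-of-range cells in an explicit overflow row. Shares sum to
100% and totals to the grand total by construction, which the tests
assert. Driver–ESV association is the Pearson correlation over cells.

## The synthetic landscape

No real rasters ship with the package; the generator produces study
areas with a *known* causal structure so the attribution pipeline can
be scored against ground truth.

- **Terrain**: three octaves of Gaussian-smoothed white noise
  (correlation length fixed at 2 cells, amplitudes halving per
  octave), rescaled to [0, 2000] m. Slope from central finite
  differences (one-sided at borders), in degrees. Smoothed Gaussian
  fields have thinner gradient tails than real mountain DEMs: at the
  default settings roughly 10% of cells exceed 15° and almost none
  exceed 25°, so the steepest gradient class stays sparse. This is a
  known limitation, not a target of calibration.
- **Climate**: temperature = 15 °C − 6.5 °C/km lapse · elevation +
  N(0, 0.5²); precipitation = 600 mm + 0.5 mm/m orographic gain ·
  elevation + smoothed noise, clipped to [300, 1600] mm.
- **Soils**: three smoothed gamma fields normalised to a Dirichlet
  simplex (silt + clay + sand = 1 exactly).
- **Human geography**: settlements (1% of cells) and a few urban
  centres placed with probability decaying in slope and elevation;
  roads as straight rasterised lines from urban centres to the border;
  rivers as steepest-descent walks from high ground. X12–X15 are
  planar Euclidean distances (m) to the nearest feature cell (0 on
  feature cells; no geodesy — single small synthetic extent).
  Population density is a Gaussian-kernel sum over settlements and
  urban centres; economic density a noisy power function of it;
  urbanization a logistic transform into [0, 1]. The kernel gridding
  of population/GDP is a stand-in for whatever dasymetric procedure a
  real study would use, not a reconstruction of one.
- **Land use**: per-cell class probabilities from a multinomial logit
  over the z-scored covariates with scenario weight matrix W (6
  classes × 15 factors) and intercepts; the probabilities *are* the
  fractional composition (closure exact by construction). Later
  epochs apply transition rules deterministically in expectation — a
  rule moves `probability` of the source fraction to the target class
  on cells meeting its condition. The default scenario encodes
  reforestation of cropland above 15° slope (10% per step) and
  construction growth within 3 km of urban centres (3% per step).
  NDVI is regenerated per epoch as the class-conditional mean mixture
  (forest 0.85, grass 0.60, crop 0.50, unused 0.20, construction
  0.15, water 0.10) + N(0, 0.05²), clipped to [0, 1].
- **Ground truth**: a scenario's driver ranking orders factors by the
  L1 norm of their weight column. `Scenario.strong_signal(factor)`
  puts a single large weight (+8) on one factor for forestland and
  zeroes everything else, giving an unambiguous dominant driver.

Because NDVI is generated *from* the land composition, it is an
endogenous proxy of the response, exactly as in real data; in
multi-driver scenarios it may legitimately out-rank the exogenous
drivers, which is why recovery guarantees are stated for the
strong-signal scenario only. What passing tests show is that the
pipeline's attribution machinery recovers a planted dominant driver
and that the forest out-predicts OLS under nonlinearity; they cannot
show that any particular real-world factor ranking is correct.

## Numerical and design choices

- Fractions, not hard classes, are canonical; hardening is a loss of
  information the method does not need.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; identical (scenario, seed) reproduce
  bit-identical bundles, forests and manifests. Manifest hashes are
  SHA-256 of logical content (array bytes, CSV text), not file bytes,
  to stay independent of container metadata.
- Degenerate inputs raise typed errors rather than returning NaN:
  zero baselines (change rate), fewer distinct values than classes
  (Jenks), zero-variance targets (forest, correlation).
- Default problem sizes: 60×60 cells for the narrative analysis
  scripts, 100×100 for the seeded recovery study, n = 5000 for the
  model-comparison study — large enough for stable forests, small
  enough to run on a laptop core in minutes.
- GeoTIFF I/O writes float32 with ModelPixelScale/ModelTiepoint tags
  via tifffile; round-trips are exact at float32 precision.

## Known limitations

- The equivalent-factor coefficients carry no uncertainty; the
  package propagates none (no sensitivity analysis of coefficients).
- Synthetic terrain under-represents very steep slopes; road and
  river geometry is schematic (straight lines, greedy descent), so
  distance fields are smoother than real network distances.
- Transition rules act in expectation (deterministic fraction
  transfer), which reproduces mean dynamics but not stochastic
  patch-level conversion.
- The forest attribution inherits the usual correlated-predictor
  caveat of permutation importance: influence shared among collinear
  covariates (e.g. elevation and orographic precipitation) is split
  between them.
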