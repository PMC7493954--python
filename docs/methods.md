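# Methods

## Scope and design

`cornsoy` implements a complete crop-type mapping workflow — harmonic
feature extraction, grid-stratified sampling, per-region random-forest
classification, cropland masking, and map validation — and pairs it with a
scene simulator so the whole chain runs against known ground truth. The
production-scale analogue of this workflow maps corn and soybean over
multi-state extents from decades of satellite imagery; here the study area
is synthetic and desk-scale, which is exactly the point: every statistic
the pipeline reports can be checked against the simulator's truth, and the
documented failure mechanisms of such maps can be reproduced as controlled
experiments.

## Harmonic features

Each band or index series at a pixel is modelled as

f(t) = c + Σ_{k=1..n} [a_k cos(2πkωt) + b_k sin(2πkωt)],  t ∈ [0, 1)

with defaults n = 2 and ω = 1.5 (5 coefficients per series; ω < 1 would
force exact annual periodicity, ω = 1.5 lets the basis track asymmetric
green-up/senescence within the year). The fitted coefficients for NIR,
SWIR1, SWIR2, and GCVI = NIR/Green − 1 are concatenated band-major in the
frozen order [c, a₁, b₁, a₂, b₂] — 20 features. The candidate registry
additionally catalogues Blue/Green/Red harmonics and 20 weather covariates
(55 candidates in total); the weather covariates are catalogued only and
never computed, since they are not part of the final feature set.

Numerical choices:

- The solver is QR-based least squares (LAPACK `gelsy`), not normal
  equations; the rank reported by the driver gates acceptance.
- A pixel-band series is "insufficient" when fewer than 2n+1 = 5 finite,
  valid observations remain, or the design is rank-deficient (e.g. all
  observations at one timestamp). Insufficient pixels are flagged, zeroed,
  and later coded 0 — never silently pseudo-inverted.
- Exactly-5-point fits are allowed; they interpolate noise but satisfy the
  stated minimum.
- Observations are sorted by time before solving, so the fit is
  bit-identical under reordering of the input.
- GCVI observations with Green ≤ 0 become NaN and are dropped
  per-observation; one bad date does not void the pixel.

## The scene simulator

Every pixel carries a true class in {1 corn, 5 soybean, 9 other,
255 non-crop}. Its reflectance in band b follows
`base_b + amplitude_b · bump(t)`, where `bump` is a Gaussian in t with
circular distance on the unit year — smooth, unimodal, and controlled by
two interpretable parameters (peak day, season width). Observation noise is
additive Gaussian per band (σ = 0.01 visible, 0.02 NIR/SWIR), truncated to
keep reflectance in [0, 2].

Default phenologies encode the ordering facts the classifier exploits,
chosen as a realistic Midwest caricature rather than fitted to any dataset:

| class    | peak day | peak GCVI | width | notes |
|----------|---------:|----------:|------:|-------|
| corn     | 0.55 (~mid July) | 2.0 | 0.09 | |
| soybean  | 0.60 (~early Aug) | 2.6 | 0.08 | later and higher than corn |
| other    | 0.42 (~late May) | 1.5 | 0.11 | winter-cereal-like, lower amplitude |
| non-crop | 0.50 | 1.2 | 0.22 | broad grass/forest-like curve |

The NIR amplitude is derived from the configured peak GCVI (given the Green
curve), so the peak index value is hit exactly. Off-season reflectance is a
fixed soil/residue spectrum shared across classes.

The acquisition schedule is 8-day revisit (two satellites) with 40%
per-observation cloud losses, which yields a median of 7 valid observations
per pixel in June–August — the availability regime the feature extraction
is designed for. Blackout windows remove all observations in a
fractional-year interval.

Across years, true classes evolve under a Markov transition table
(corn→soy 0.55, soy→corn 0.65, "other" sticky at 0.70, non-crop static), so
rotation statistics are non-degenerate and regional crop mixtures drift
realistically from their initial values. Reference labels are the true
classes with 2% of crop pixels flipped to another crop class, emulating
reference-map error; both training and evaluation see the noisy labels, as
they would in production.

One RNG substream per artifact (classes, noise, clouds, label flips, mask
flips, sampling, split, each forest), keyed by name and year under the
master seed: adding a new draw never perturbs existing ones, and identical
seeds reproduce every artifact bit for bit.

What the simulator does **not** emulate: radiative transfer or crop-growth
physiology, spatial autocorrelation of fields and weather (pixels are
independent given class), georeferencing and real administrative
boundaries, sensor-specific band responses, and label noise that is
spatially structured rather than i.i.d. Passing tests therefore show the
pipeline's machinery is correct and its failure modes move in the right
direction — not that real-data accuracy would match the synthetic numbers,
which are optimistic because the classes are well separated by
construction.

## Stress scenarios

- `midseason_blackout`: adds a blackout window spanning roughly July 1 to
  September 30 (widened if needed to cover both crop peaks). Missing the
  peak removes the feature that distinguishes soybean's high GCVI maximum,
  so soybean is predicted as corn. Applied at prediction time only.
- `delayed_planting`: shifts corn's peak 70% of the way toward soybean's,
  merging the two phenologies; corn is predicted as soybean. Prediction
  time only.
- `low_revisit`: 12-day revisit with 45% cloud losses, calibrated so the
  median June–August valid count drops to ~4 — a single-satellite year.
  The whole pipeline re-runs under this schedule.

## Study conditions and problem sizes

The default configuration is a 64×64-pixel scene (pixel ≈ 3.1 km, so the
extent spans a 4×4 grid of 50 km sampling cells and four ~10,000 km²
"counties" with distinct crop mixtures), five years (2014–2018) with the
earliest year held back entirely as a hindcast test, 250 points per grid
cell, an 80/20 record-level split within training years, and 500-tree
forests — the sampling and classifier settings of the production workflow
on a scene small enough to run end to end in well under a minute. The
split unit is the (point, year) record; splitting by point instead would
remove a small cross-year leakage channel but the reference convention
counts records.

Masking uses cropland masks derived from the 2014 and 2016 label rasters
with a 2% flip rate (emulating out-of-date land-cover products); each
year's map is masked by the latest mask year ≤ the map year, with years
before the first mask falling forward to the earliest one.

## Validation statistics

Confusion is restricted to pixels where both maps hold a crop code
{1, 5, 9}; unclassified and non-crop pixels are excluded symmetrically and
counted. User's/producer's accuracy are per-class precision/recall. Area
agreement uses the raw-value R² on predicted vs reference areas (no
refitted regression; negative when predictions underperform the reference
mean); the squared Pearson correlation r² is exposed separately and never
conflated with it. Rotation fractions count current-corn pixels by prior
class, excluding priors other than corn/soybean from both numerator and
denominator. Area trends are OLS slopes of area on calendar year. Any
statistic with a zero denominator is returned as an explicit None, is
excluded from summaries, and is never coerced to 0 or NaN.

## Known limitations

- Class separability is set by four hand-chosen phenology curves; accuracy
  numbers characterize the pipeline, not any sensor or region.
- Regional crop mixtures converge toward the rotation table's stationary
  distribution over long simulations; region contrasts are strongest in
  early years.
- Raster I/O uses plain multi-band TIFF with JSON sidecars; there is no
  geospatial referencing, reprojection, or tiling beyond row blocks.
- The forests use the classifier library's default hyperparameters apart
  from tree count; no calibration or class weighting is attempted.
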