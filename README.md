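# cornsoy

A synthetic end-to-end testbed for harmonic-regression crop-type mapping:
the workflow that turns multi-date, cloud-masked satellite reflectance into
annual corn/soybean/other maps, exercised entirely on a scene simulator
that emulates Midwest crop phenology and Landsat-like acquisition gaps.

It is aimed at people building or validating crop-classification pipelines
who want every stage — feature extraction, sampling, classification,
masking, and map validation — testable against known ground truth, and
want the documented failure modes of such products reproducible on demand.

## The method

Each spectral band or vegetation index at a pixel is treated as a
time-dependent function *f(t)* over the calendar year (*t* ∈ [0, 1)) and
summarized by ordinary least squares on a truncated Fourier basis:

```
f(t) = c + Σ_{k=1..n} [ a_k cos(2πkωt) + b_k sin(2πkωt) ]
```

with order *n* = 2 and period control *ω* = 1.5, i.e. 5 coefficients per
series. The final feature vector stacks NIR, SWIR1, SWIR2, and
GCVI = NIR/Green − 1 (a greenness index that does not saturate at high leaf
area and separates corn from soybean), giving 20 features per pixel. A fit
requires at least 5 valid observations; pixels that fall short are coded 0
(unclassified).

Training points are drawn 250 per 50 km grid cell for spatial balance,
labelled from a reference crop map (with configurable label noise),
split 80/20 within the training years, and used to fit one 500-tree random
forest per region. Predicted maps use codes {0 unclassified, 1 corn,
5 soybean, 9 other crop, 255 non-crop}; non-cropland is overridden to 255
by the last available cropland mask (an earlier-year mask applies to later
years until a newer one exists).

Validation follows the standard categorical-map suite: overall accuracy,
per-class user's/producer's accuracy (precision/recall), regional area
agreement via the raw-value coefficient of determination
R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)² (computed on areas directly, so bias is
penalized and R² can be negative), soybean→corn rotation fractions between
consecutive years, and linear area trends.

The scene simulator gives every pixel a class-specific seasonal reflectance
curve (soybean peaking later and higher in GCVI than corn; an
early-peaking winter-cereal-like "other" class), samples it on an 8-day
revisit schedule with random cloud losses, and supports three stress
scenarios reproducing documented failure mechanisms: a mid-season imagery
blackout, delayed corn planting, and a sparse-revisit year.

## Worked example

```
python analysis/01_simulate.py          # scenes, labels, regions -> scratch/run/
python analysis/02_extract_features.py  # 20-band harmonic feature rasters
python analysis/03_sample_and_train.py  # stratified samples + per-region forests
python analysis/04_predict_and_validate.py
python analysis/05_stress_scenarios.py
```

The validation step prints (seed 0):

```
held-out overall accuracy:  0.9894
hindcast overall accuracy:  0.9807
corn     user's 0.9893  producer's 0.9901
soybean  user's 0.9860  producer's 0.9924
area R2 vs label-derived areas: {
  "corn_train_years": 0.979, "corn_test_years": 0.998,
  "soybean_train_years": 0.965, "soybean_test_years": 0.985 }
rotation r^2 (pred vs label): 0.9777
```

Held-out accuracy is agreement with the (noisy) reference labels on the
20% of training-year records never shown to the forests; hindcast accuracy
is the same statistic on the earliest simulated year, which contributes no
training data at all — the train-on-recent, predict-the-past design. The
area R² values compare per-region crop areas aggregated from the masked
maps against label-derived areas; the rotation r² compares predicted and
label-derived soybean→corn rotation fractions across regions and year
pairs. The stress step shows soy→corn confusions jumping 13 → 129 under a
mid-season blackout and corn→soy confusions 10 → 556 under delayed
planting, while a sparse-revisit year lowers held-out accuracy.

Equivalently, `cornsoy run --seed 0 --out results/run` executes all stages
at once, and per-stage subcommands (`simulate`, `extract`, `sample`,
`train`, `predict`, `validate`) resume from the artifact directory.

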