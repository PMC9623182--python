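# Methods

This note documents the models and procedures implemented in `uavpheno`,
the synthetic study conditions under which they are tested, and the design
choices made where the underlying methodology leaves room.

## The phenotyping pipeline

**Coordinate model.** All rasters share one convention: 0-based, row-major
pixels with the origin at the top-left, and an affine transform mapping a
pixel index to the world coordinates of that pixel's *center* (ESRI
world-file semantics). A pixel belongs to a plot iff its center lies
strictly inside the plot ring; this center-point rule is deterministic and
is checked against an exhaustive point-in-polygon oracle in the tests. All
layers are assumed co-registered (as a GCP-controlled photogrammetric
workflow provides); no reprojection is performed.

**Chromaticities and indices.** Indices are computed per pixel on
normalized chromaticities and averaged over the plot afterwards
(per-pixel-then-average, not index-of-mean-DN). Pixels with zero band sum
are flagged invalid rather than propagating NaN into the chromaticity
arrays; denominator-zero pixels of individual indices (VARI at g+r=b,
GRRI at g=0) are invalid in that index only. Two registry quirks are kept
deliberately: GLA differs from GLI only in one numerator sign and is
implemented exactly as defined rather than "corrected", and GRRI is the
chromaticity ratio r/g (identical to the DN ratio R/G by scale
invariance). Plot aggregation uses *all* plot pixels by default; an
option restricts means to vegetation pixels.

**Vegetation segmentation.** The orthomosaic route computes EXG = 2g−r−b
and takes a single global threshold by maximizing the between-class
variance of a 256-bin histogram (Otsu's criterion); vegetation is
EXG > threshold. Ties among cuts — which occur as plateaus across empty
histogram bins — resolve to the smallest maximizing cut, with a 1e-9
relative tolerance so float round-off cannot move the cut off the
plateau. Constant-EXG scenes (e.g. bare soil rendered without noise) have
no defined threshold; the segmenter returns an empty mask with a warning
by default, or raises on request.

**Ground-photo coverage (VCEA).** The reference coverage measurement
emulates nadir photos of a 1.3 m white box: (1) candidate pixels with HSI
hue in a green window (default 60°–180°) and saturation ≥ 0.1; (2) EXG
thresholded by the same maximum-inter-class-variance criterion; (3)
8-connected components smaller than 25 px removed (the morphological
threshold). The Otsu threshold in stage 2 is computed over the whole box
interior rather than the hue-window candidates: after the hue pre-filter
the candidate histogram is essentially single-class, and a class-splitting
threshold computed on it would bisect the vegetation itself. The hue
window, saturation floor and minimum component area are free parameters
of the algorithm; the defaults above are package choices, stated in the
configuration and overridable, since the operator sequence does not pin
them down. Near-white pixels (intensity > 0.85, saturation < 0.15) are
treated as the reference frame and excluded from the coverage
denominator.

**Height and canopy volume.** CHM = DSM_stage − DSM_bare, with negative
differences clamped to zero (they arise from DSM noise and have no
physical meaning). Plot height is the mean CHM over vegetation-mask
pixels inside the plot, in cm; if the mask is empty the all-pixel mean is
used with a warning, and a 90th-percentile variant is available for
sensitivity analysis, since "average plot height" does not specify the
pixel population. CV = CC × H inherits H's units (cm).

**Modeling.** The calibration/validation partition is fixed by the trial
design: replicates 1 and 3 train (32 plots), replicate 2 validates (16).
Feature screening uses Pearson correlation with two-sided t-test p-values
(df = n−2), no multiple-testing correction; the "VIs" feature set is the
five indices with the largest |r| *on the training partition only* (using
all data for selection would leak the validation fold; this is noted as a
possible minor divergence from practice where the choice is ambiguous),
with ties broken by registry order. Models: OLS with intercept;
KNN regression with k = 5, uniform weights, Euclidean distance on
z-scored features (scaler fit on the training fold); random forest with
500 trees, ⌈p/3⌉ candidate features per split, bootstrap resampling,
seeded. k, the scaling, and the forest shape are conventional regression
defaults, configurable. NRMSE is RMSE divided by the *mean* of the
observed values (×100): back-solving published accuracy tables of this
workflow gives ratios matching the observed-mean denominator and not the
range. Summary statistics use the sample (n−1) standard deviation and
CV% = SD/mean × 100.

## The synthetic study conditions

The generator is first-class code, not a fixture: its defaults *are* the
study conditions of the test suite.

**Design.** 48 plots of 32.5 m² (6.5 m × 5 m) on an 8-column grid with
1 m alleys: a density zone (T0–T2 × two varieties × 3 replicates = 18), a
nitrogen zone (N0–N3 × two varieties × 3 = 24) and a potassium zone
(K0/K2 × one variety × 3 = 6).

**Truth sampling.** Per-plot PNC is treatment-driven: standardized
treatment scores (monotone increasing in N level, mildly decreasing in
density, near-null for potassium and variety) explain 75% of the PNC
z-variance, Gaussian plot noise the rest; draws are clipped to each
stage's observed envelope (S1: 2.09–4.50, S2: 1.61–4.00, S3: 1.86–3.74 %
dry mass, with the matching stage means and SDs). H and CC are then drawn
as z_x = r·z_PNC + √(1−r²)·ε in population-standardized coordinates with
independent noises, so the target correlation r is realized up to
clipping; defaults are r = 0.7 at S1 weakening to 0.5 at S3, reflecting
the observed decay of morphology–nitrogen coupling as the season
progresses. The independence of the two noises is what makes CV = CC × H
a better single predictor than either factor (signal adds, noise
averages) — the generator reproduces that ordering rather than assuming
it.

**Rendering.** Soil is a fixed brown chromaticity (0.45, 0.32, 0.23) at
DN-sum 300; vegetation green chromaticity increases affinely with plot
PNC (g = 0.46 + 0.025·(PNC − 3), clipped to [0.40, 0.50]) at DN-sum 260,
so every chromaticity-based index carries a recoverable PNC signal by
construction. At S3 a senescence shift moves 0.035 of chromaticity mass
from green to red, degrading EXG separability — the mechanism behind the
tested late-season accuracy loss. Per-channel DN jitter (SD 8 DN) and
per-pixel DSM noise (SD 0.01 m) are the default noise conditions. Plants
are disks (radius 0.20–0.40 m) packed until the plot's vegetation-pixel
count *exactly* equals the target; the last disk is trimmed to its pixels
nearest its center, and the stored truth is read off the final mask, so
coverage recovery tests face no packing stochasticity. The bare-soil DSM
is a deterministic gentle slope plus low-amplitude relief around 36 m
elevation; vegetation pixels sit true_H above it. Ground photos re-render
the same truth at 4× resolution inside a white frame. The default
orthomosaic ground sample distance is 0.10 m — coarser than real surveys
flown at 20 m altitude (~0.01 m), chosen so a plot still contains ~3,250
pixels (ample for coverage fractions and mean heights) while full scenes
render in under a second; `SceneConfig.gsd` scales it.

**What the generator does not emulate.** No BRDF, shadows, illumination
gradients or radiometric miscalibration; no 3-D plant architecture,
row structure, mutual occlusion or mixed soil/vegetation boundary pixels
beyond quantization; no georeferencing error between stages. Passing
recovery tests therefore demonstrates the correctness of the algorithms
under controlled conditions, not field-level accuracy: real extraction
errors (height RMSE of a few cm, coverage RMSE of a few percent,
validation R² near 0.7–0.8) are substantially larger than the synthetic
ones reported by the acceptance script.

**Linear recovery benchmark.** A separate generator produces a balanced
replicated dataset (16 treatment profiles × 3 replicates, 3 features)
with a known linear response and noise variance set so the population
R² is exactly 0.8. With a 16-point validation fold the sampling
distribution of validation R² = 1 − SSE/SST has a standard deviation of
about 0.07–0.08 (χ² fluctuation of the validation noise sum of squares
plus the signal–noise cross term), so individual seeds frequently land
outside ±0.1 of the population value; the benchmark reports the in-band
rate and median across 50 seeds, and a permuted-response control that
must show no skill.

## Numerical choices and degenerate inputs

* Otsu: 256 bins over the input range; constant input raises a
  degenerate-input error; smallest maximizing cut with 1e-9 relative
  plateau tolerance.
* Chromaticity: zero-sum pixels flagged, never NaN; index rasters use NaN
  as nodata and zonal means are NaN-aware, reporting valid-pixel counts.
* Raster round-trips are bit-exact for integer data; affines survive to
  1e-9 via a JSON metadata block, with standard GeoTIFF scale/tiepoint
  tags written alongside for interoperability and honored on read.
* Empty plot∩raster intersections warn and return empty rather than
  raising; coverage over zero valid pixels raises.
* MLR refuses rank-deficient designs and n ≤ p; KNN refuses k > n_train.
* Random-forest predictions are bit-reproducible for a fixed seed and row
  order; row permutation changes the bootstrap draws, so order invariance
  holds only up to tree-averaging noise.

## Known limitations

* The treatment effect sizes on PNC are generator defaults chosen to be
  agronomically plausible; only pooled per-stage statistics constrain
  them, so zone-level contrasts should not be read as field estimates.
* Index–PNC coupling in rendered scenes is strong (plot-mean indices are
  nearly noise-free averages over thousands of pixels), so model R² on
  synthetic scenes saturates near 1 and only *relative* comparisons
  between feature sets and stages are meaningful.
* The VCEA implementation is one faithful instantiation of the published
  operator sequence (HSI pre-filter, EXG threshold, area filter); the
  original's exact parameter values are not recorded, so agreement is
  verified against the generator, not against the original instrument.
* Rotated (non-axis-aligned) affines are supported in memory and via the
  JSON metadata block, but the GeoTIFF scale/tiepoint tags are written
  only for north-up grids.
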