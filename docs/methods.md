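# Methods

## Pipeline model

The package implements the standard two-epoch supervised land-cover
change workflow on co-registered rasters sharing a single grid
(row-major, top-left origin, 30 m pixels by default):

1. **Scene filtering and compositing.** Dated six-band reflectance
   scenes carry a QA bitmask whose low five bits flag fill, dilated
   cloud, cirrus, cloud, and cloud shadow (the Landsat Collection 2
   QA_PIXEL/CFMASK layout). Scenes above a cloud-cover threshold
   (default 50 %, inclusive) or outside a closed date window are
   dropped; the per-epoch composite is, per pixel and band, the median
   of QA-valid observations (even counts: mean of the two central
   values). The median was chosen because it is the common robust
   reducer for reflectance compositing; a mean reducer is available
   behind the `reducer` switch and the choice is recorded in output
   metadata.
2. **Classification.** Single-pixel regions of interest (ROIs) are
   sampled per class from a reference map — default counts 300
   (forest/shrubs), 100 (mangrove), 50 (bare soil), 100 each (wetland,
   pine, agriculture, water), 850 total — and split stratified 70/30
   into train/test (train count = round-half-up of 0.7 × class count).
   A random forest (scikit-learn, 100 trees, default depth, fixed seed)
   is fit on the six composite bands and predicts every valid pixel;
   invalid pixels become nodata. Tree count and depth are exposed in
   config; no hyperparameter search is attempted.
3. **Elevation post-processing.** Ordered rules `(source class,
   comparator, threshold m, target class)` reassign physically
   implausible predictions. Defaults: mangrove > 20 m, wetland > 100 m,
   water > 400 m, each to forest/shrubs — the canonical corrections for
   coastal classes predicted at altitude. The rule list is fully
   overridable; per-rule change counts are logged. The default list is
   idempotent because its target class is never a later source.
4. **Accuracy.** Independent validation ROIs (default 100 per class,
   50 for water; 650 total) yield a 7×7 confusion matrix (rows =
   reference), from which overall accuracy, Cohen's kappa, and
   per-class accuracy are computed. Per-class accuracy defaults to
   producer's (diagonal / reference-row total); user's accuracy is also
   computed, since published per-class figures often do not state which
   convention they use.
5. **Change quantification.** Compositions use each epoch's own
   classified pixels inside the mask; transition tables use pixels
   classified in both epochs. This convention makes marginal
   reconstruction (row/column sums of the transition table) an exact
   count-level identity, which is also how the packaged reference
   tables cross-validate. Percentages are carried at full precision and
   rounded to two decimals only at report time.
6. **Significance.** See below.

## Bootstrap change test

Observed statistic: `Δ_c = pct_c(epoch 2) − pct_c(epoch 1)` per class,
in percentage points. Null: every valid pixel in each epoch receives an
independent random category — from the pooled two-epoch empirical
distribution (default) or uniform over the seven classes — and `Δ_c` is
recomputed; 1 000 replicates by default. Decision rule: significant iff
the observed `Δ_c` lies strictly above the 99th or below the 1st
linear-interpolation percentile of the null. A two-sided empirical
p-value with the add-one convention,
`p = (1 + #{|Δ_null| ≥ |Δ_obs|}) / (n_reps + 1)`, is reported alongside
and cannot be exactly zero at finite replicates.

Two choices deserve note. First, "random re-assignment" is implemented
per pixel rather than as a label permutation within an epoch: permuting
labels leaves each epoch's composition unchanged and would make the
null degenerate; independent per-pixel assignment is the reading that
produces a usable distribution of random changes. Second, because the
pixels are re-assigned independently, each replicate's per-epoch class
counts are exactly one multinomial draw of that epoch's valid-pixel
count, so the implementation samples the multinomial counts directly —
distributionally identical to materializing random maps, and what makes
a 500-world calibration experiment run in seconds. The pooled null is
the default as the less extreme of the two models.

The test inherits the usual caveat of pixel-level resampling: it
ignores spatial autocorrelation, so on strongly clumped real landscapes
the null is anti-conservative. A block/spatial bootstrap would be the
extension; it is out of scope here.

## Synthetic worlds

The generator emulates the ingredients of the two-epoch Landsat-style
study design so every stage has known ground truth:

- **Truth map**: one Gaussian-smoothed random field (correlation length
  `patch_scale`, default 8 px) thresholded at the cumulative quantiles
  of the requested class proportions (default uniform, 1/7 each) —
  neutral-landscape-style clumping with near-exact proportions.
- **Change process**: pixelwise-independent Markov draw from a 7×7
  row-stochastic kernel. The default kernel keeps classes at 0.88–0.97
  persistence except agriculture, which moves mass 0.35 to
  forest/shrubs — the dominant signal of the motivating system. Because
  change is spatially independent, the expected transition table equals
  the kernel weighted by epoch-1 composition, an analytic recovery
  target.
- **Scenes**: per-pixel reflectance = class mean (six bands, fixed
  well-separated spectra, pairwise distance > 0.12) + iid Gaussian
  noise (`noise_sd` 0.04), clipped to [0, 1]; 3 scenes per epoch.
  Clouds are random bright discs (radius 4–12 px) stamped until a
  target fraction (default 0.15) is covered, each with a dark shadow at
  a fixed offset; both set their QA bits, and the scene header's cloud
  percentage is the realized cloud-disc fraction (shadows flag QA but
  are not "cloud cover"). Scene dates fall inside per-epoch year
  windows (1984–1988; 2020–2021).
- **Elevation**: smooth surface, 20–320 m, with mangrove/wetland/water
  pixels pinned below 5 m — coastal classes sit near sea level in the
  landscapes this emulates, which is the physical premise of the
  elevation rules (and keeps them from destroying correct predictions
  of those classes).
- **Masks**: `protected` is a smoothed-blob mask at a target fraction
  (default 0.17); `od` (host-plant potential distribution) is a
  smoothed field with a bonus on forest/shrub pixels, thresholded to
  0.25 of the region, so roughly a fifth to a quarter of it falls
  inside protected areas — the regime of the motivating study;
  `od_in_protected` is the intersection.

All randomness derives from one seed through spawned child generators,
so a world bundle is bit-reproducible.

What the generator does **not** emulate: sensor radiometry and
cross-sensor differences, seasonal phenology, topographic illumination,
spatially contagious change, mixed pixels, and polygon (multi-pixel)
ROIs. Passing tests therefore demonstrate that the pipeline's
statistics are implemented correctly and recover known truth under
idealized but non-trivial noise, clouds, and class imbalance — not that
any particular real-world accuracy would be achieved.

## Reference tables

A transcription of the published Cuban composition (7 classes × 4
areas × 2 epochs) and transition (49 rows × 4 areas) tables is packaged
as CSV, frozen with sha256 checksums verified at load. The consistency
computation applies the marginal-reconstruction rule to each area's
transition matrix and compares with the printed compositions: across
all 56 reconstructions the maximum disagreement is 0.02 percentage
points, within the ±0.05 attributable to two-decimal rounding. Two
columns (Cuban agriculture in both epochs, Cuban water in 2020)
reconstruct exactly.

## Problem sizes and numerical choices

- Default analysis grid 128×128 (tests use 64–256); chosen as the
  smallest size at which per-class transition percentages are estimated
  to well under one percentage point and the classifier sees every
  class amply.
- Bootstrap calibration experiment: 500 Monte-Carlo null worlds at
  128×128 with 200 replicates each; per-class rejection rates land in
  [0.005, 0.05] around the nominal 0.02 two-tailed level (200
  replicates make the percentile estimates slightly coarse, which
  inflates the rate above 0.02 but keeps it within the band).
- Percentiles: linear interpolation (numpy default); strict
  inequalities in the decision rule.
- Degenerate inputs: empty masks, single-class training data, kernels
  that are not row-stochastic, and class codes outside {0..7} are hard
  errors; ROIs on invalid pixels are dropped with a logged count, never
  silently.
- Raster storage is TIFF with grid metadata (pixel size, origin,
  nodata, epoch label) as JSON in the ImageDescription tag; write→read
  roundtrips are identity on values and grid. The package does not
  reproject — all rasters must share one grid.

## Known limitations

- No spatial-autocorrelation-aware null (see above).
- No area-adjusted accuracy estimators or kappa variance.
- Single-grid assumption; no datum or resampling support.
- The elevation rule defaults are the package's own; any
  application to real data should supply rules matched to its region.
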