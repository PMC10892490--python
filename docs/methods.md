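# Methods

## Problem and model

The package maps vegetation health in polar moss beds from six-band UAV
reflectance rasters. The target is a per-pixel labelling into five
classes (healthy moss, stressed moss, moribund moss, lichen,
non-vegetation). Moss health expresses itself spectrally: healthy turf is
green with a pronounced NIR plateau, stress raises red reflectance
(photoprotective carotenoids), and moribund turf is pigment-depleted,
grey and spectrally flat. The workflow therefore combines band
reflectances, ratio-type vegetation indices and local texture statistics,
and classifies them with two complementary models plus their stacked
combination.

## Spectral indices

Twenty-one indices are implemented over the blue/green/red/red-edge/NIR
bands; the thermal plane never enters an index and participates only as a
raw feature. Two published renderings required a decision:

- **MSAVI** is implemented in its standard closed form
  `(2·NIR + 1 − sqrt((2·NIR+1)² − 8·(NIR − R))) / 2`; the discriminant
  `(2N−1)² + 8R` is non-negative for any non-negative reflectance.
- **ARVI** defaults to the conventional form with `rb = 2R − B`,
  `(NIR − rb)/(NIR + rb)`. A literal transcription of the degenerate
  printed variant — which algebraically collapses to
  `(NIR + 2B)/(NIR − 2B)` — is available behind the
  `arvi_as_printed` switch for comparison.

Zero-denominator pixels (e.g. SRI with R = 0, SIPI with NIR = R, RGI/GCI
with G = 0) are flagged nodata rather than emitting infinities, so
downstream feature tables stay finite. Inputs are accepted as [0, 1]
floats or integer digital numbers with a declared scale; the EVI, OSAVI
and GOSAVI additive constants assume the [0, 1] convention.

Useful algebraic identities are enforced by tests: NGRDI = −GRVI,
EXGR = EXG − EXR, and GRVI = (RGI − 1)/(RGI + 1) wherever G ≠ 0.

## Texture statistics

Sliding-window mean, variance, skewness and kurtosis are computed from
windowed raw moments accumulated with a box filter (reflection padding at
edges). The default window is 5×5 — the smallest support at which the
third and fourth moments are usably stable — and is configurable. Nodata
pixels are excluded from each window's sample; windows with fewer than 3
valid pixels become nodata. Conventions: population (biased) estimators,
Fisher kurtosis (normal → 0), and skewness = kurtosis = 0 on
zero-variance windows. The central moments are recovered from raw moments,
which is numerically safe for reflectance-scale values in float64.

## Correlation screening

Moss health is correlated with features after ordinal encoding along the
degradation gradient (healthy = 1, stressed = 2, moribund = 3) — the
minimal assumption for a categorical state with a documented stress
ordering; the encoding is recorded in the report. Pearson correlation is
used; zero-variance features report r = 0 with a degenerate flag.

## Tiling and stitching

Grids use 0-based, half-open, row-major pixel windows with stride
`floor(tile·(1 − overlap))`; the final row/column of tiles is anchored
flush to the raster edge rather than padding partial tiles, so coverage
is total and the CNN input size stays fixed. Where overlapping tiles
disagree, per-class probabilities are averaged over covering tiles,
renormalised, and argmaxed; argmax ties break toward the lower class ID
for determinism. Polygon labels are burned by the pixel-centre rule with
later polygons overwriting earlier ones.

## Stage 1: gradient-boosted trees

XGBoost (`multi:softprob`, hist) with max depth 10, learning rate 0.02,
250 rounds, subsample 0.8, colsample_bytree 0.8, gamma 0, alpha 0,
lambda 1. The booster always emits 5-class probability vectors, even when
training labels miss a class. The default feature set is the 6 raw bands,
the eight-index preset (GNDVI, MSAVI, LCI, GRVI, RGI, NDRE, EVI, SIPI)
and the four texture statistics per raw band (38 planes). Feature
importance is reported as gain. No class reweighting is applied by
default; inverse-frequency weights are available behind
`class_weighting` for scenes with scarce healthy-moss labels. Inference
runs in 700×700-pixel batches; because the model is per-pixel and the
texture planes are computed once over the full raster, tiled and untiled
predictions are identical (asserted in tests).

## Stage 2: encoder-decoder CNN

The network is a symmetric U-shape: four encoder blocks (two 3×3
same-padded convolutions + ReLU, dropout, 2×2 max-pool), a bottleneck,
and four decoder blocks (2×2 stride-2 transposed convolution, skip
concatenation, two convolutions), closed by a 1×1 convolution to 5
logits. Defaults follow the tuned optimum: 128×128 patches at 30 %
overlap, no input pre-filter, 25 % of patches held out, filter ladder
64-128-256-512 with a 1024 bottleneck, dropout 0.2, Adam at 1e-3, batch
25, 400 epochs, sparse-categorical cross-entropy. Design points:

- **Numpy engine.** The layers (im2col convolution, pooling, transposed
  convolution, dropout, Adam) are implemented in-package with explicit
  reverse-mode gradients, verified against finite differences; float32
  NCHW. This keeps the stage fully deterministic per seed.
- **Masked loss.** Label-0 pixels contribute neither loss nor gradient,
  so sparse polygon labels can supervise full patches; unlabeled is not
  conflated with non-vegetation.
- **Standardization** statistics (per-channel mean/SD) come from training
  patches only and are frozen into the checkpoint.
- **Method 2 input** uses stage-1 *probability* planes (not hard
  one-hot): probabilities preserve uncertainty and make the
  uniform-prediction degenerate case well behaved; `stage1_onehot`
  provides the hard-label alternative. The raw bands are kept alongside
  the probability channels (6 + 5 = 11).
- Downsampling is max-pool, upsampling transposed convolution, no batch
  normalisation, ReLU throughout; kernel size 3 (configurable).
- The `scaled("small")` preset (ladder 16-32-64-128/256, ≤ 50 epochs)
  is the desk-scale configuration used by the test suite and the
  verification script; the full configuration remains the documented
  default. Scaled runs in this package use 160–192 px scenes, 64×64
  patches, 30–50 epochs and learning rate 2e-3, chosen as the smallest
  problem sizes at which the recovery properties are cleanly expressed.

## Evaluation

Per-class metrics follow the one-vs-rest counting forms given above;
F1 is computed as `2TP/(FP+2TP+FN)`, algebraically the harmonic mean of
precision and recall (asserted to 1e-12 on random matrices). TN is
tracked per class for completeness although no reported metric uses it.
Zero-support classes report 0 with an `undefined` flag rather than NaN so
report schemas stay stable. K-fold cross-validation supports two fold
units: `pixel` (stratified rows; the GBM default) and `tile` (whole tiles
per fold; the CNN default). Pixel-level folds of spatially correlated
rasters are optimistically biased — neighbouring, nearly identical pixels
land in different folds — which is why tile folds exist and why
pixel-fold CV accuracy should not be compared against held-out-region
scores. Area reports multiply class pixel counts by the pixel footprint
(0.001024 m² at the 3.2 cm GSD default) and express percentages over the
labeled part of the region, with unlabeled area reported separately.

## Synthetic scenes

The generator draws a spatially coherent class map by Gaussian-smoothing
white noise (correlation length 8 px) and thresholding at the quantiles
of the class priors (10/20/25/20/25 % for healthy/stressed/moribund/
lichen/non-vegetated), then adds class-mean reflectance signatures plus
additive Gaussian noise (optionally spatially correlated), clipped to
[0, 1]. Signatures follow the degradation gradient, so NDVI of the class
means decreases healthy > stressed > moribund > non-vegetated by
construction; the thermal band is generated but uninformative (identical
class means), mirroring its exclusion from all indices. Difficulty
presets change only the noise SD: easy 0.02 (≥ 5 SD separation in at
least one band for every class pair), moderate 0.05, hard 0.10. Sparse
training labels are axis-aligned rectangles (4–12 px sides)
rejection-sampled to lie inside a single truth class until ~30 % of
pixels are labeled; this exercises the polygon→mask path with exactly
verifiable geometry and makes the exported GeoJSON rasterize bit-exactly
to the exported mask.

What the generator does *not* emulate: BRDF and illumination gradients,
orthomosaic stitching seams, sensor noise correlated across bands,
mixed pixels at class boundaries, and the irregular shapes of real
labeling polygons. Passing recovery tests on these scenes demonstrates
that the pipeline's machinery is correct and that each stage can recover
structure it is designed for — not that real-scene accuracy will match.

## Numerical and degenerate-input choices

- Probability renormalisation after stitching guards against float drift;
  argmax ties go to the lower class ID.
- Confusion matrices ignore truth-0 pixels; predictions outside 1..5
  (nodata) count in no cell.
- Window statistics snap window counts to integers before the <3-valid
  test to avoid box-filter float fuzz.
- All entry points are seeded; one global seed fans out to per-stage
  seeds via `SeedSequence` so stages are independently reproducible.

## Known limitations

- The numpy CNN is CPU-bound and intended for desk-scale rasters and the
  scaled preset; the full 400-epoch/1024-filter configuration is faithful
  but slow without an accelerator.
- Georeferencing is carried as an affine transform only; no reprojection
  or warping is performed.
- GeoTIFF I/O stores band names and the transform in the TIFF description
  tag (or a sidecar YAML on read); CRS metadata of third-party rasters is
  not interpreted.
- Correlation screening reports Pearson r on the ordinal encoding;
  rank-based alternatives are not implemented.
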