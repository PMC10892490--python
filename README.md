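# mosshealth

Mapping the health of Antarctic moss beds and lichen cover from drone
multispectral imagery. Ground surveys of these fragile communities are
invasive and labour-intensive; `mosshealth` turns already-rectified
six-band UAV orthomosaics (blue, green, red, red-edge, NIR, thermal) into
per-pixel maps of five classes — **Healthy Moss (1), Stressed Moss (2),
Moribund Moss (3), Lichen (4), Non-Vegetation (5)** — using a two-stage
machine-learning workflow:

1. **Feature extraction** — 21 spectral vegetation indices (NDVI, GNDVI,
   MSAVI, EVI, SRI, ARVI, SIPI, GCI, NDRE, LCI, DVI, TVI, NGRDI, OSAVI,
   GOSAVI, EXG, EXR, EXGR, RGI, GRVI, ENDVI), plus sliding-window mean,
   variance, skewness and kurtosis texture planes per band.
2. **Stage 1** — an XGBoost per-pixel classifier (max depth 10, learning
   rate 0.02, 250 estimators, subsample 0.8, colsample_bytree 0.8)
   emitting 5-class probability planes and a gain-based feature ranking.
3. **Stage 2** — a U-shaped encoder-decoder CNN (implemented in pure
   numpy, four encoder blocks with a 64→1024 filter ladder, 3×3 kernels,
   dropout 0.2, Adam, masked sparse-categorical cross-entropy) trained on
   128×128 patches with 30 % overlap. *Method 1* feeds the six bands;
   *Method 2* is the stacked ensemble: the stage-1 probability planes are
   concatenated as five extra input channels (11 in total).
4. **Evaluation** — confusion matrices and per-class
   precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(FP+2TP+FN),
   IoU = TP/(TP+FP+FN), k-fold cross-validation, and class-area reports
   (m² and percentages at a given ground sampling distance).

A seeded synthetic-scene generator produces five-class landscapes with
spatially coherent patches, class-specific spectral signatures ordered
along the moss degradation gradient, and sparse rectangle labels, so the
whole pipeline can be exercised and validated without any field data.

## Worked example

```bash
mosshealth synth --difficulty easy --size 192 --seed 7 --out scene/
mosshealth gbm-train --input scene/stack.tif --labels scene/labels.tif \
    --seed 7 --out gbm.json
mosshealth gbm-predict --model gbm.json --input scene/stack.tif --out seg.tif
mosshealth evaluate --truth scene/truth.tif --pred seg.tif
```

The final command prints the per-class report for the segmented map
(values from this exact run):

```
                Precision  Recall  F1-Score     IoU  Support
healthy_moss       0.9997  1.0000    0.9999  0.9997     3687
stressed_moss      0.9991  0.9999    0.9995  0.9989     7372
moribund_moss      0.9999  1.0000    0.9999  0.9999     9216
lichen             1.0000  0.9988    0.9994  0.9988     7373
non_vegetation     0.9999  1.0000    0.9999  0.9999     9216
```

i.e. on an easy synthetic scene the stage-1 classifier recovers all five
classes nearly perfectly. Class supports reflect the scene's class
priors; note the truth raster includes the ~30 % of pixels the model was
trained on, so this table slightly flatters held-out performance — the
test suite scores held-out pixels only (macro-F1 ≥ 0.95). The same library calls are available in Python via
`mosshealth.build_feature_table`, `mosshealth.train_gbm`,
`mosshealth.run_method`, `mosshealth.evaluate`, etc.

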