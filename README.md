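# ct2bmd

Bone mineral density (BMD) regression from CT texture. The pipeline has
four stages:

1. **Imaging** — read a CT slice (single-frame DICOM, or lossless PNG/TIFF
   with a JSON rescale sidecar), cut out a rectangular or elliptical region
   of interest (ROI), report mean/SD Hounsfield units (HU), and quantize
   gray levels.
2. **Texture** — gray-level co-occurrence matrices (GLCMs) at orientations
   0°/45°/90° with unit displacement, averaged, then five second-order
   statistics: energy, entropy, contrast, homogeneity, correlation.
3. **Calibration** — an ordinary-least-squares line through phantom inserts
   of known hydroxyapatite-equivalent density converts HU to volumetric
   density (the regression target).
4. **Neural network** — a from-scratch 5–40–1 feedforward network
   (tanh hidden layer, linear output, full-batch gradient descent at
   learning rate 0.19, min–max scaling to [−1, 1] fitted on the training
   split, 70/15/15 split, early stopping on validation MSE with
   best-weight restoration) maps the five features to BMD.

A synthetic module generates trabecular-bone-like phantoms (thresholded
Gaussian random fields) with exactly known density, rendered both as a
sharp "QCT" image and a blurred/noisier "clinical CT" image, so the whole
chain — including the train-on-QCT / evaluate-on-clinical experiment — runs
with no external data.

## CLI

All coordinates are 0-based, row-major, with half-open ROI extents
`[origin, origin + size)`.

```bash
# ROI statistics
ct2bmd roi --image slice.png --roi roi.json --out roi_stats.json

# texture features (CSV row: contrast,correlation,energy,homogeneity,entropy,bmd)
ct2bmd features --image slice.png --roi roi.json --ng 8 --d 1 --thetas 0,45,90 --out features.csv

# phantom calibration
ct2bmd calibrate --inserts inserts.json --out cal.json

# train / predict / evaluate
ct2bmd train --features features.csv --out model.json --seed 42 --lr 0.19
ct2bmd predict --model model.json --features new.csv --out pred.csv
ct2bmd evaluate --pred pred.csv --truth truth.csv

# synthetic data and the full experiment
ct2bmd simulate --n 300 --size 128 --seed 7 --out-dir data/
ct2bmd run --config experiment.json --out-dir results/
```

`ct2bmd run` executes the end-to-end experiment: simulate phantoms,
extract features, train on the QCT renderings, and evaluate predictions on
the clinical renderings of the held-out test split. The JSON report
contains per-split correlation coefficients and MSE (`training.metrics`,
the analog of the per-split and overall training-phase scatter metrics),
per-epoch MSE curves (`training.curves`, the validation-performance
analog), and the cross-scanner result (`clinical_evaluation`, the
clinical-vs-reference scatter analog). Every report carries the seed and a
hash of the scientific configuration.

A nine-row sample feature/BMD table is packaged and available as
`ct2bmd.load_sample_dataset()`.

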