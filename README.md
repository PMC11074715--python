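# contourtl

Contour-based preprocessing and transfer-learning classification of brain
MRI slices for binary tumor detection ("tumor" vs "no tumor"), with a
thresholding tumor-segmentation stage, deterministic augmentation,
reproducible dataset partitioning and a seven-metric evaluation suite.

The package is aimed at people studying classical preprocessing +
fine-tuned-CNN pipelines for small medical-imaging datasets. Every stage is
exercisable end-to-end on **synthetic phantom images** (bright elliptical
"brain" on a dark background, optionally carrying a brighter disc "tumor"),
so no clinical data or download is needed to run, test or extend it.

## The pipeline

1. **Contour cropping** — grayscale (BT.601), Gaussian smoothing, global
   binarization (pixels `< T` → 0, else 255), erosion/dilation cleanup,
   retrieval of the outer boundary of every 8-connected component
   (Moore-neighbour tracing with collinear-run chain compression), and
   cropping of the *original* image to the bounding box of the
   largest-area component — the brain.
2. **Enhancement + segmentation** — resize to 144×144, affine intensity
   enhancement `clip(α·f + β, 0, 255)`, automatic global threshold by
   maximizing between-class variance of the histogram (Otsu's criterion),
   then grey-level-preserving segmentation

       f(x, y) = f(x, y)  if f(x, y) ≥ threshold
                 0         otherwise

   — surviving pixels keep their intensity; the output is not binarized.
3. **Deterministic augmentation** — rotations R(θ), horizontal/vertical
   flips (mirror of the X or Y axis) and zoom in/out, organised in fixed
   catalogues: an 8-op plan (identity, 90°/180°/270°, both flips,
   zoom 1.25/0.8) and a 36-op plan (rotations × flips × zooms), so a
   253-image set expands to exactly 2024 or 9108 images and a 3000-image
   set to 24000.
4. **Partitioning** — 80/20(+20 % of the pool) and 70/30 "unseen case"
   schemes with ceiling rounding, stratified by label, grouped by
   augmentation source (all variants of one image stay in one split), with
   a hard leakage guard for the unseen scenario.
5. **Classifier** — a VGG-16-style network: 13 convolutions (3×3, stride 1)
   in five blocks with five 2×2/stride-2 max-pools (144 → 72 → 36 → 18 →
   9 → 4, so a 4×4×512 feature map), the first ten convolutions frozen and
   three fine-tuned, then three dense+dropout blocks and a 2-way softmax.
   Training uses RMSprop (default learning rate 2·10⁻⁵), sparse categorical
   cross-entropy and early stopping with best-weight restore. The engine is
   a self-contained numpy implementation (`contourtl._nn`) with exact
   analytic gradients (finite-difference-checked in the tests).
6. **Evaluation** — sensitivity, specificity, precision (PPV), NPV,
   accuracy, F1 and ROC-AUC from the confusion matrix / scores, plus
   `solve_confusion`, which reconstructs the unique integer confusion
   matrix behind a row of printed (2-decimal) metric values.

## Worked example

Run a complete "unseen case" experiment on noise-free phantoms: train and
validate (70/30) on one generated dataset, test on a second, disjoint one,
with the reduced CPU-scale model:

```python
from contourtl.pipeline import RunConfig, run_experiment

report = run_experiment(RunConfig(
    out_dir="demo_run", seed=42, scenario="unseen",
    phantom_counts=(70, 70), phantom_test_counts=(30, 30),
    phantom_noise_sd=0.0,
    model="reduced", image_side=48, channels=1,
    learning_rate=1e-3, max_epochs=15, batch_size=16, patience=15,
    val_fraction=0.3,
))
print(report)
```

Output (about 5 s on one CPU core):

```json
{
  "seed": 42,
  "scenario": "unseen",
  "sizes": {"train": 98, "validation": 42, "test": 60},
  "confusion_matrix": {"tp": 30, "fp": 0, "tn": 30, "fn": 0},
  "metrics": {
    "sensitivity": 100.0, "specificity": 100.0, "precision": 100.0,
    "npv": 100.0, "accuracy": 100.0, "f1": 100.0, "roc_auc": 1.0
  },
  "stopped_epoch": 15,
  "best_epoch": 15
}
```

Reading: 140 training-pool phantoms were cropped, segmented and split
98/42; the model then classified all 60 images of the held-out, disjoint
test dataset correctly (TP=30 tumor, TN=30 normal), so every metric is 100
and the ROC-AUC is 1.0. Phantoms are deliberately easy at zero noise —
this demonstrates the plumbing, not clinical performance (see
`docs/methods.md`).

The same experiment is available from the shell:

```sh
contourtl phantoms --n-tumor 70 --n-normal 70 --seed 1 --out data/
contourtl crop --in data --out cropped --threshold 45 --kernel 5
contourtl segment --in cropped --out segmented --alpha 1.3 --beta 10
contourtl augment --manifest data/manifest.csv --plan x8 --out augmented
contourtl split --manifest augmented/manifest.csv --scheme 80-20 --seed 1 --out split.csv
contourtl run --config run.yaml          # full pipeline from a YAML config
```

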