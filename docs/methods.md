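# Methods

This note records the models, conventions and design decisions behind
`contourtl`, in the order the pipeline runs.

## Phantom generator

A phantom is an axis-aligned bright ellipse ("brain") on a dark background
with an optional brighter disc ("tumor") strictly inside it, plus additive
Gaussian noise clipped to [0, 255]. These are the simplest shapes that
exercise every downstream stage: contour detection needs a blob on a
background, cropping needs a non-centred blob (the brain centre is jittered
uniformly by ±5 % of the image size), and threshold segmentation needs a
three-mode intensity histogram. The tumor disc centre is sampled inside the
ellipse shrunk by the tumor radius, which guarantees containment.

Default sampling ranges (one image ≈ 160–192 px square):

| parameter | default | why |
|---|---|---|
| background intensity | 5–15 | dark MRI air background; safely below the crop threshold of 45 |
| brain intensity | 60–80 | mid-grey soft tissue; above the crop threshold |
| tumor intensity | 200–240 | hyperintense lesion |
| brain semi-axes | 48–68 px | brain fills roughly ⅔ of the frame |
| tumor radius | 12–20 px | a few percent of the brain area |
| noise σ | 3 grey levels | mild acquisition noise |

The intensity ranges are deliberately arranged so that the tumor–brain
contrast (≥ 120 levels) dominates the brain–background contrast (~60
levels). A single global between-class-variance threshold then latches onto
the tumor rather than the brain outline — the behaviour the segmentation
stage is meant to display — which one can verify from the variance
arithmetic: with a ~21 % background / ~73 % brain / ~6 % tumor crop, the
tumor-vs-rest split has the larger between-class variance precisely when
the tumor–brain gap is roughly twice the brain–background gap.

What phantoms do **not** emulate: MRI physics (bias fields, T1/T2
contrast, partial voluming), anatomical texture, skull/fat shells, 3-D
geometry, and pathology diversity. A pipeline that is perfect on phantoms
has demonstrated its mechanics, nothing more; accuracy numbers obtained on
phantoms say nothing about clinical data.

## Contour cropping

Grayscale conversion uses BT.601 luma weights (0.299, 0.587, 0.114) with
round-half-up. Smoothing is a separable normalized Gaussian (default 5×5;
σ derived from the kernel size by the usual `0.3·((k−1)/2 − 1) + 0.8`
convention) with edge replication. Binarization maps pixels `≥ T` to 255,
else 0, with default `T = 45`; morphology is 2 erosions then 2 dilations
with a 3×3 square element. Only the element size is canonical; the
threshold and iteration counts are conventional defaults for
brain-on-black cropping and are all config-overridable.

External contours are traced per 8-connected component with
Moore-neighbour tracing started at the component's first raster pixel.
Termination is by repeated (pixel, backtrack-direction) state, which is
robust for every component shape including one-pixel-wide spurs; the traced
boundary is then chain-compressed (collinear horizontal/vertical/diagonal
runs collapse to their endpoints). Each contour carries the hole-filled
area of its component; the largest-area contour wins (ties: first in
raster order) and the *original* image is cropped to its inclusive
bounding box, so no grey-level information is lost before segmentation.
Coordinates are (row, col), 0-based, inclusive, everywhere.

## Enhancement and segmentation

Images are resized to 144×144 (bilinear, aspect ratio deliberately not
preserved — the classifier wants a fixed raster). Enhancement is affine,
`clip(round(α·f + β))` with defaults α = 1.3, β = 10: a one-knob contrast
gain plus brightness offset, monotone in intensity.

The segmentation threshold is the grey level maximizing between-class
variance of the histogram (Otsu's criterion) over the split
`{f < t} / {f ≥ t}`, ties resolved to the smallest qualifying level, with a
`DegenerateHistogram` error on constant images. A fixed manual threshold
can be supplied instead. Segmentation itself preserves grey levels: pixels
below the threshold become 0, the rest keep their value. It is idempotent,
never increases a pixel, and its zero-set grows monotonically with the
threshold — all property-tested.

By default the *segmented* image (not the enhanced crop) is what feeds the
classifier; `segment_enabled: false` in the run config switches to the
enhanced crop. With the default phantom settings, segmentation of a tumor
image keeps essentially the tumor disc (Dice ≈ 0.99 against the
generator's mask in the tests, asserted at ≥ 0.5), while a normal image
keeps the whole brain — a very strong class signal.

## Augmentation

Ops compose as rotate → flip → zoom inside one `AugmentOp`. Right-angle
rotations and flips are exact pixel permutations; oblique rotations
resample bilinearly about the centre with zero fill (black background, like
the imaging background). Zoom-in crops the central `side/factor` window
and rescales; zoom-out shrinks and zero-pads; shape is always preserved.

The 8× and 36× plan cardinalities are fixed by the target dataset sizes
(253 → 2024, 3000 → 24000, 253 → 9108); the specific op catalogue inside
each plan (which angles, which zoom factors) is this package's choice,
constrained to rotation/flip/zoom ops, pairwise distinct, identity first.
Augmented images always inherit the source label, and the output manifest
records `source` and `op` so later stages can group by provenance.

## Partitioning

`partition_sizes` uses ceiling on the test count, ceiling on the validation
count (taken from the post-test pool), remainder to train — the only
rounding rule consistent with the reference allocation
9108 → (5828, 1458, 1822). For the 24000-image 70/30 pool the text rule
gives (16800, 7200, 0); a published table lists 4800 validation / 3840
test for the 80/20 3000×8 case, which contradicts the stated rule
(val = 20 % of training ⇒ 4800 test / 3840 val); this package follows the
rule and notes the discrepancy here.

Splitting is stratified by label (largest-remainder apportionment keeps
each class within one item of its overall share) and grouped by
augmentation source by default, because splitting after augmentation
would place near-duplicates of one image on both sides of the train/test
boundary. Grouped assignment matches target sizes to the nearest whole
group; `group_by_source=False` restores exact row-level sizes. The unseen
scenario additionally refuses to run if the train and test manifests share
any path or source (`LeakageError`).

## Classifier and training

The numpy engine implements Conv2D (im2col + matmul, 'same' zero padding,
stride 1), 2×2/stride-2 max-pooling with floor on odd dims, dense layers,
ReLU, inverted dropout, softmax cross-entropy with max-subtraction, and
RMSprop (ρ = 0.9, ε = 1e-7). Gradients are analytic and checked against
central finite differences at 1e-6 tolerance in the tests. Freezing is
implemented by exempting a layer from optimizer updates while still
back-propagating through it, so frozen weights remain bit-identical —
asserted in the tests after real optimization steps.

The default spec is the 13-conv / 5-pool stack with the first 10
convolutions frozen. The dense head is (512, 256, 64) with dropout 0.5
after each dense layer, then a 2-unit softmax; the head widths are not
canonical (the architecture's published trainable-parameter total does not
pin them down) and are config-exposed. A stated input of "14 × 144 × 3" is
treated as a typo for 144×144×3, consistent with the 144×144 resize stage.
Batch size 32, max 30 epochs, patience 5 are defaults, all configurable.
`ModelSpec.reduced()` keeps the same grammar at phantom scale (five
single-conv blocks of width 8–32, one dense block, dropout 0.2) and is
what the CPU-scale end-to-end tests train from random initialization.
Pretrained feature weights are consumed from an `.npz` checkpoint when
provided; nothing in the package trains or downloads them.

Early stopping: training halts when validation loss has not improved for
`patience` consecutive epochs (strict improvement; learning rate 0 is
legal and stops at epoch `patience + 1`), and the best-validation weights
are restored. A learning rate of 1e-3 is used for the random-init reduced
model in the tests; 2e-5 is the fine-tuning default.

## Evaluation

Positive class is "tumor" (label 1). Sensitivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP), precision = 100·TP/(TP+FP),
NPV = 100·TN/(TN+FN), accuracy = 100·(TP+TN)/N, F1 = harmonic mean of
precision and sensitivity (≡ 100·2TP/(2TP+FP+FN), property-tested).
ROC-AUC is the pair-ordering probability with ties counted half
(delegated to scikit-learn; verified against an all-pairs counting oracle).
Rounding is half-up to two decimals and applied only at reporting.
Zero-denominator metrics are reported as `None` with a warning — never as
0, which would silently corrupt averages.

`solve_confusion` enumerates every (TP, TN) pair given the class totals
and accepts exactly one matrix whose rounded metrics match all supplied
printed values (errors on zero or multiple matches). With totals 1240/784
and printed sensitivity 100 / specificity 98.60 it returns
(TP, FP, TN, FN) = (1240, 11, 773, 0), from which the remaining published
row values (precision 99.12, NPV 100, accuracy 99.46, F1 99.56) follow
identically.

## Reproducibility and problem sizes

One top-level seed per run; stage seeds derive from SHA-256 of
(seed, stage-tag), all below 2³¹, so altering one stage's randomness never
shifts another's. Phantom images are bit-reproducible under (spec, seed)
and round-trip PNG exactly.

Test-suite problem sizes are chosen for single-core desk scale: oracle
equivalence runs on masks ≤ 64×64, histograms ≤ 24×24 and score lists
≤ 200; the architecture census runs one optimization step of the full
13-conv model on a single 144×144 image; the end-to-end experiment trains
the reduced model on 200 noise-free phantoms (140 train-pool / 60 disjoint
test) at 48×48 for ≤ 15 epochs over three seeds, asserting ≥ 90 % test
accuracy on the majority of seeds. Full-scale fine-tuning of the 13-conv
network on thousands of 144×144 images is out of scope for this engine;
the architecture is exact, the training loop is the same code path, only
the scale differs.

## Known limitations

- Phantoms are radically simpler than clinical MRI; results on them are
  mechanism checks, not performance claims.
- The global-threshold segmentation assumes a single dominant bright
  lesion; multifocal or hypointense lesions would defeat it.
- The engine is single-threaded numpy: correct and exact, but not suited
  to training the full-width VGG-16 stack at dataset scale.
- The threshold-selection algorithm is a between-class-variance maximizer
  adopted as a stand-in where the original procedure is underspecified;
  a fixed manual threshold is available as the escape hatch.
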