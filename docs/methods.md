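# Methods

## Problem and model

The package localizes the two hip joints in an anteroposterior pelvic
radiograph as square, loose-fitting boxes. Because one radiograph contains
exactly one or two large, non-overlapping targets, the detector is a
deliberately simplified single-shot multibox design: a single convolutional
predictor on one 7 × 7 feature layer, one aspect ratio (1:1), and a small
set of scales chosen from data. The anchor at cell (i, j) with scale s is
centered at ((i+0.5)·32, (j+0.5)·32) px of the 224-px model input and has
side s·32; anchors are never clipped at borders (clipping would shrink the
corner anchors and break the coverage guarantee — out-of-bounds area is
handled naturally by IoU).

### Coordinate conventions

Continuous 0-based pixel coordinates throughout; boxes are stored as
center + side and converted to half-open corner intervals only for areas.
Preprocessing (8-bit min–max normalization, zero-padding appended
right/bottom, bilinear resize to 224) is recorded as an affine transform
`x' = (x + pad)·scale`, so boxes map analytically (never rasterized) and
round-trip to 1e-6 px.

### Anchor design

The ROI ratio r = box side / image long side normalizes ROI sizes across
datasets of very different resolutions. Given a coverage band
[r_lo, r_hi] — default (0.100, 0.314), matching the 10–30% band where hip
ROI ratios concentrate — K equally spaced scales are placed between
r_lo·224/32 and r_hi·224/32, each rounded to one decimal. The one-decimal
rounding is load-bearing: it is what maps (0.100, 0.314) onto the printed
set {0.7, 1.0, 1.3, 1.6, 1.9, 2.2}. Rounding collapse (duplicate scales)
raises an error advising smaller K or wider bounds. Bounds are explicit
inputs (with percentile helpers in the CLI) because no fixed percentile
convention reproduces them from data.

A note on coverage guarantees: with a 32-px anchor stride, a box centered
at a cell corner sits (16, 16) px from every anchor center; even the
largest in-band box (side 67.2) then reaches at most IoU ≈ 0.42 against
the best anchor, and the smallest (22.4) only ≈ 0.04. "The anchors can
identify appropriate ROIs" therefore cannot mean "some anchor always
overlaps at IoU ≥ 0.5"; it holds in the matched-training sense (each
ground truth is always assigned its argmax-IoU anchor) and in the
detection sense (the head regresses offsets, so predicted boxes reach
IoU ≥ 0.5 regardless of the anchor's own overlap). The corresponding
strict-IoU property test is kept in the suite and fails, documenting the
geometric fact.

## Detector and training

Backbones. `tiny`: five stride-2 3×3 conv–BatchNorm–ReLU blocks
(channels 8, 16, 32, 64, 64; ~60k parameters) taking 1 × 224 × 224 to the
7 × 7 map, implemented in NumPy with explicit backward passes; training is
bit-reproducible for a fixed seed on one device. `resnet101_pretrained`
names the full-scale configuration; it requires an external deep-learning
framework with ImageNet weights and is not constructible here.

Head. One 3 × 3 conv emits per cell and scale two class logits
(background, hip) and four offsets. Offsets use the standard multibox
encoding dcx = (g−a)/a_w/0.1, dw = log(g_w/a_w)/0.2. The hip-logit bias is
initialized at −3 so early training is background-dominated.

Matching. Each ground truth's argmax-IoU anchor is forced positive (ties
to the lower index; if two truths share an argmax the higher-IoU one keeps
it). Other anchors are positive above IoU 0.35 for their argmax truth.
Anchors in [0.25, 0.35) are ignored — excluded from the classification
loss. The laxer-than-usual threshold and the ignore band exist because the
single 32-px-stride layer is coarse relative to the smallest ROIs: with a
0.5 threshold a small box often has only its forced positive while
visually identical neighboring-scale anchors are labeled background, which
trains cleanly but generalizes poorly (held-out average IoU ≈ 0.68 versus
≈ 0.84 with the defaults). Both thresholds are config-exposed;
`iou_ignore=None` restores plain threshold matching.

Loss and optimization. L = (1/N_pos)[Σ_pos smoothL1 + CE over positives
and the per-image hardest 3·N_pos negatives]; with no positives the loss
degrades to background classification. Adam (lr 1e-3, decay ×0.1 at epoch
24), batch size 8, 30 epochs, decoupled weight decay available but 0 by
default (it did not improve held-out performance). One master seed fans
out to independent init/shuffle/split streams. `train` can hold out a
validation fraction and track best-validation weights; the default trains
on all provided images because validation-loss selection picked worse
checkpoints than the final weights in held-out experiments.

Inference. Decode all anchors, threshold on confidence (softmax hip
probability), greedy NMS at IoU 0.45, keep top-k = 2, symmetrize decoded
w/h to side = max(w, h), and map back through the inverse preprocessing
transform. For evaluation the reporting convention is exactly top-2 boxes
per image with no confidence cutoff: the per-ROI accounting (ROIs =
2 × images, with reported minimum IoU below 0.5) presumes every image
contributes two predictions. The `detect` tool default keeps
conf_thresh = 0.5 for interactive use.

## Evaluation protocol

Per image, predictions are paired 1-1 to ground truths greedily by IoU
(ties: higher confidence, then lower gt index); unmatched ground truths
count as IoU 0, which keeps totals equal to 2 × images. The report carries
average/minimum IoU over ground truths, average/minimum confidence over
reported detections, the count of ROIs under IoU 0.5, and AP50. AP uses
all-points interpolation (the precision envelope), selected over 11-point
interpolation and switchable; a detection is a true positive when it
reaches IoU 0.5 against a still-unclaimed ground truth in its image.

## Synthetic data generator

Each sample is a grayscale image with a smooth two-axis background
gradient, a faint pelvic-ring ellipse, additive Gaussian noise
(sd 6 on the 8-bit scale), and two bright filled discs placed roughly
symmetrically about the vertical midline. Image long sides follow three
heterogeneity profiles — high-resolution (1616–4280 px), low-resolution
(466–1080 px) and mixed (225–4256 px) — mirroring the spread between
hospital film archives, study archives, and web-collected images. The
ground-truth box side is ratio r · long side with r ~ U(0.10, 0.30); the
disc diameter is box side / margin with margin 1.3 jittered ±10% to
emulate annotator variability in loose-fitting labels, and the box center
is jittered up to 3% of the side ("approximately centered"). Optional
artifact modes add text blocks, implant-like bright cores with stems,
crescent-shaped collapsed heads, and dislocation offsets (the box follows
the disc). Boxes are guaranteed disjoint and disc/background contrast
clears 3× the noise sd, so the detection task is well-posed.

What the generator does not emulate: anatomy beyond the two discs and a
ring, projection physics, gridlines/collimation, pathology appearance, or
annotator disagreement beyond the margin jitter. Passing the synthetic
experiments therefore demonstrates that the pipeline's geometry, matching,
training and metrics are correct and that the detector solves an easier
analog of the radiographic task — not that this exact network would reach
the same numbers on clinical images.

The margin jitter bounds attainable IoU: the visible disc does not
determine the labeled side exactly, so even a perfect regressor averages
about IoU 0.90 against jittered labels; the scaled-down experiment's
average of ≈ 0.84 sits close to that ceiling.

## Problem sizes and numerical choices

The scaled-down experiment trains on 400 mixed-profile images for 30
epochs and evaluates on 100 held-out images — sizes chosen so a full run
completes in minutes on one CPU while keeping 200 evaluation ROIs.
Percentiles use linear interpolation between order statistics; size
summaries default to sample standard deviation; constant images normalize
to 0; non-square boxes read from COCO files are symmetrized to
side = max(w, h) with a warning. All stochastic stages derive their
streams from one master seed via seed-sequence spawning; seeds stay below
2^31.

## Known limitations

Single-class, single-layer detection only (by design); the NumPy training
loop is CPU-bound and not meant for full-scale radiograph corpora; the
`resnet101_pretrained` backbone option is declared but not constructible
without an external framework; DICOM ingestion and windowing are out of
scope.
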