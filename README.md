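# hiproi

Anchor-based detection of hip regions of interest (ROIs) in anteroposterior
pelvic radiographs (PXRs), built as a complete, labeling-light pipeline:
data-driven anchor design from ROI-size statistics, a simplified
single-feature-layer multibox detector, the IoU/confidence/AP50 evaluation
protocol, and a synthetic pseudo-radiograph generator so every stage runs
end-to-end with no external data.

## Who this is for

Medical-image analysis groups building "two-step" systems (detect the joint,
then classify it) who need a reproducible, parameter-transparent ROI
detector: the anchor sizes are derived from dataset statistics instead of
copied from natural-image defaults, and every detection carries a
confidence score.

## The method

Radiographs are normalized to 8-bit grayscale, zero-padded to a square and
resized to 224 × 224. The model input is split into a 7 × 7 grid of
32 × 32-px cells; each cell carries K square (1:1) anchors with side
`scale · 32`. The normalizer that makes datasets comparable is the ROI
ratio

```
r = (square ROI side) / (long side of the image)
```

Given a coverage band [r_lo, r_hi] observed in the data (hip ROIs lie
mostly at 10–30% of the image side), the design procedure places K equally
spaced scales between `r_lo·224/32` and `r_hi·224/32`, rounded to one
decimal. The default band (0.100, 0.314) with K = 6 yields

```
scales = {0.7, 1.0, 1.3, 1.6, 1.9, 2.2}       (294 anchors = 7·7·6)
```

whose smallest and largest anchors cover 10% and 31.4% of the input side.
A compact CPU-trainable convolutional backbone (stride-2 conv/BN/ReLU
blocks, ~60k parameters) reduces the input to the 7 × 7 feature map; one
3 × 3 convolutional head predicts per-anchor class scores and SSD-style
box offsets (variances 0.1/0.2). Training uses smooth-L1 localization plus
cross-entropy with 3:1 hard negative mining; matching forces each ground
truth's argmax-IoU anchor positive, adds anchors above IoU 0.35, and
ignores the band [0.25, 0.35). Evaluation reports average/minimum IoU over
ground truths, average/minimum confidence, the count of ROIs below IoU
0.5, and AP50 with all-points interpolation.

## Worked example

```bash
hiproi e2e --n-images 300 --size-profile mixed --epochs 30 --seed 7 \
       --out runs/demo
```

generates 300 synthetic pseudo-PXRs (image long sides 225–4256 px, two
bright "femoral head" discs each, square loose-fit boxes at 10–30% of the
long side), trains the tiny detector on 240 of them (~2 minutes on one
CPU), reports top-2 boxes per image on the held-out 60, and prints the
evaluation row:

```
 n_images  n_rois  avg_iou  avg_confidence  min_iou  min_confidence  n_below_half_iou     ap50
       60     120 0.810307        0.909931 0.448625        0.033692                 4 0.965223
```

Read: 120 annotated hips in 60 held-out images; the detected boxes overlap
the ground truth by 81% IoU on average, 4 fall below the IoU-0.5 cutoff,
and ranking all detections by confidence gives average precision 0.97 at
that cutoff (held-out accuracy rises further with the training-set sizes
used in `scripts/acceptance.py`). `runs/demo/` holds the report,
detections (CSV + COCO JSON), size summary and the effective config. The
same pipeline is available stepwise: `simulate`, `stats`,
`design-anchors`, `train`, `detect`, `evaluate`.

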