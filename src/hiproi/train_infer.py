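"""Seeded training loop, 90/10 splitting, and inference.

Training precomputes, per image, the model-space tensor and the
anchor-matching targets (both depend only on the fixed anchor set), then
runs mini-batch Adam on the multibox loss.  One master seed fans out to
independent init and shuffle streams, so identical seeds give bit-identical
loss curves and detections on one device.

Inference decodes every anchor, keeps detections above a confidence
threshold, applies greedy NMS, keeps the top-k (default 2: one box per
hip), symmetrizes the decoded width/height back to a square side, and maps
the result to original-image coordinates through the inverse preprocessing
transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .anchor_design import AnchorSet, GridSpec, design_scales, generate_anchors
from .detector_core import SsdDetector, encode_boxes, match_anchors, multibox_loss
from .evaluation import pairwise_iou
from .imaging_io import BoxAnnotation, GeomTransform, Radiograph, box_to_model_space, preprocess

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "Checkpoint",
    "Detection",
    "make_split",
    "default_anchors",
    "train",
    "detect",
    "nms",
]

#: fixed grayscale input standardization (8-bit scale)
PIXEL_MEAN = 0.449
PIXEL_STD = 0.226


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation image-id lists, fixed once per experiment."""

    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    seed: int
    frac: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.valid_ids):
            raise ValueError("train and validation ids overlap")


def make_split(image_ids: Sequence[str], seed: int, frac: float = 0.9) -> SplitSpec:
    """Random one-time split; |train| = round(frac * n), deterministic per seed."""
    ids = sorted(set(image_ids))
    if len(ids) < 2:
        raise ValueError("make_split requires at least 2 image ids")
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(len(ids))
    n_train = int(round(frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = tuple(ids[i] for i in perm[:n_train])
    valid = tuple(ids[i] for i in perm[n_train:])
    return SplitSpec(train, valid, seed=seed, frac=frac)


@dataclass(frozen=True)
class TrainConfig:
    """Training defaults for the tiny backbone (all exposed, all logged)."""

    epochs: int = 30
    batch_size: int = 8
    lr: float = 1e-3
    lr_decay_epoch: int = 24  # epoch index at which lr is multiplied by lr_decay
    lr_decay: float = 0.1
    weight_decay: float = 0.0
    valid_frac: float = 0.0  # held-out fraction for best-weight selection (0: train on all)
    neg_pos_ratio: int = 3
    # the 7x7 single-layer grid is coarse relative to the smallest ROIs, so
    # matching is laxer than classic two-stage settings: positives from 0.35
    # up, with a [0.25, 0.35) ignore band keeping near-matches out of the
    # background class
    iou_pos: float = 0.35
    iou_ignore: float | None = 0.25
    variances: tuple[float, float] = (0.1, 0.2)
    model_size: int = 224
    grid_n: int = 7
    ratio_bounds: tuple[float, float] = (0.100, 0.314)
    n_scales: int = 6
    backbone: str = "tiny"
    seed: int = 0


def default_anchors(config: TrainConfig) -> AnchorSet:
    grid = GridSpec(config.model_size, config.grid_n)
    scales = design_scales(*config.ratio_bounds, k=config.n_scales, grid=grid)
    return generate_anchors(scales, grid)


@dataclass
class Checkpoint:
    """Self-describing model state: config + anchors + weights + loss logs."""

    config: TrainConfig
    anchors: AnchorSet
    weights: list[np.ndarray]
    best_weights: list[np.ndarray]
    loss_log: list[float] = field(default_factory=list)
    valid_loss_log: list[float] = field(default_factory=list)

    def build_model(self, best: bool = False) -> SsdDetector:
        model = SsdDetector(
            self.anchors, backbone=self.config.backbone, seed=self.config.seed,
            variances=self.config.variances,
        )
        model.load_state_arrays(self.best_weights if best else self.weights)
        return model

    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "anchors": json.loads(self.anchors.to_json()),
            "loss_log": self.loss_log,
            "valid_loss_log": self.valid_loss_log,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": w for i, w in enumerate(self.best_weights)}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            n = sum(1 for k in data.files if k.startswith("w"))
            weights = [data[f"w{i}"] for i in range(n)]
            best = [data[f"b{i}"] for i in range(n)]
        cfg_doc = meta["config"]
        cfg_doc["variances"] = tuple(cfg_doc["variances"])
        cfg_doc["ratio_bounds"] = tuple(cfg_doc["ratio_bounds"])
        config = TrainConfig(**cfg_doc)
        anchors = AnchorSet.from_json(json.dumps(meta["anchors"]))
        ckpt = cls(config, anchors, weights, best)
        ckpt.loss_log = meta["loss_log"]
        ckpt.valid_loss_log = meta["valid_loss_log"]
        return ckpt


@dataclass(frozen=True)
class Detection:
    """A decoded hip box in original-image pixels with its confidence."""

    image_id: str
    cx: float
    cy: float
    side: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if not all(np.isfinite([self.cx, self.cy, self.side])):
            raise ValueError("detection coordinates must be finite")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _prepare_image(img: Radiograph, model_size: int) -> tuple[np.ndarray, GeomTransform]:
    model_img, t = preprocess(img, model_size=model_size)
    x = (model_img.pixels.astype(np.float32) / 255.0 - PIXEL_MEAN) / PIXEL_STD
    return x[None, :, :], t


def _prepare_targets(
    boxes: Sequence[BoxAnnotation],
    t: GeomTransform,
    anchors: AnchorSet,
    config: TrainConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    gt_model = np.array(
        [
            (mb.cx, mb.cy, mb.side, mb.side)
            for mb in (box_to_model_space(b, t) for b in boxes)
        ]
    )
    match = match_anchors(
        gt_model, anchors.boxes, iou_pos=config.iou_pos, iou_ignore=config.iou_ignore
    )
    labels = match.labels
    loc_targets = np.zeros((anchors.count, 4))
    pos = labels >= 0
    if pos.any():
        loc_targets[pos] = encode_boxes(
            gt_model[labels[pos]], anchors.boxes[pos], variances=config.variances
        )
    max_iou = float(match.iou_matrix.max()) if match.iou_matrix.size else 0.0
    return labels, loc_targets, max_iou


def train(
    samples: Sequence[tuple[Radiograph, Sequence[BoxAnnotation]]],
    config: TrainConfig = TrainConfig(),
    anchors: AnchorSet | None = None,
    valid_samples: Sequence[tuple[Radiograph, Sequence[BoxAnnotation]]] | None = None,
) -> Checkpoint:
    """Train the detector; returns a self-describing checkpoint.

    ``samples`` pairs each radiograph with its ground-truth boxes (>= 1 per
    image).  A per-epoch validation loss selects the best-validation
    weights, kept alongside the final ones: with ``valid_samples`` given
    those are used, otherwise ``config.valid_frac`` of the training images
    is held out internally (the standard 90/10 convention).  Set
    ``valid_frac=0`` to train on everything; then both weight slots hold
    the final weights.
    """
    if not samples:
        raise ValueError("train requires a non-empty training set")
    if any(len(boxes) == 0 for _, boxes in samples):
        raise ValueError("every training image needs at least one box")
    anchors = anchors or default_anchors(config)
    if valid_samples is None and config.valid_frac > 0 and len(samples) >= 10:
        ids = [img.source_id for img, _ in samples]
        split = make_split(ids, seed=config.seed, frac=1.0 - config.valid_frac)
        train_ids = set(split.train_ids)
        valid_samples = [s for s in samples if s[0].source_id not in train_ids]
        samples = [s for s in samples if s[0].source_id in train_ids]

    xs, labels_all, locs_all = [], [], []
    best_overlap = 0.0
    for img, boxes in samples:
        x, t = _prepare_image(img, config.model_size)
        labels, loc_targets, max_iou = _prepare_targets(boxes, t, anchors, config)
        best_overlap = max(best_overlap, max_iou)
        xs.append(x)
        labels_all.append(labels)
        locs_all.append(loc_targets)
    if best_overlap < config.iou_pos:
        raise RuntimeError(
            f"no ground-truth box overlaps any anchor at IoU >= {config.iou_pos} "
            f"(best {best_overlap:.3f}): the anchor scales and the ROI-ratio band "
            "of the data are incompatible; re-run anchor design on this "
            "dataset's ratio distribution"
        )
    val_batches = None
    if valid_samples:
        val_batches = []
        for img, boxes in valid_samples:
            x, t = _prepare_image(img, config.model_size)
            labels, loc_targets, _ = _prepare_targets(boxes, t, anchors, config)
            val_batches.append((x, labels, loc_targets))

    ss = np.random.SeedSequence(config.seed)
    init_seed, shuffle_ss = ss.spawn(2)
    model = SsdDetector(
        anchors,
        backbone=config.backbone,
        seed=int(init_seed.generate_state(1)[0] % (2**31)),
        variances=config.variances,
    )
    shuffle_rng = np.random.default_rng(shuffle_ss)
    optimizer = model.make_optimizer(lr=config.lr, weight_decay=config.weight_decay)

    n = len(xs)
    x_stack = np.stack([x[0] for x in xs])[:, None, :, :]
    labels_stack = np.stack(labels_all)
    locs_stack = np.stack(locs_all)

    ckpt = Checkpoint(config, anchors, [], [])
    best_val = np.inf
    for epoch in range(config.epochs):
        if epoch == config.lr_decay_epoch:
            optimizer.lr = config.lr * config.lr_decay
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            cls_logits, loc_pred = model.forward(x_stack[idx], train=True)
            loss, d_cls, d_loc = multibox_loss(
                cls_logits, loc_pred, labels_stack[idx], locs_stack[idx],
                neg_pos_ratio=config.neg_pos_ratio,
            )
            model.backward(d_cls, d_loc)
            optimizer.step(model.grads())
            epoch_loss += loss * len(idx)
        ckpt.loss_log.append(epoch_loss / n)
        if val_batches is not None:
            v_loss = 0.0
            for x, labels, loc_targets in val_batches:
                cls_logits, loc_pred = model.forward(x[None], train=False)
                loss, _, _ = multibox_loss(
                    cls_logits, loc_pred, labels[None], loc_targets[None],
                    neg_pos_ratio=config.neg_pos_ratio,
                )
                v_loss += loss
            v_loss /= len(val_batches)
            ckpt.valid_loss_log.append(v_loss)
            if v_loss < best_val:
                best_val = v_loss
                ckpt.best_weights = model.state_arrays()
    ckpt.weights = model.state_arrays()
    if not ckpt.best_weights:
        ckpt.best_weights = ckpt.weights
    return ckpt


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float = 0.45) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, scores desc."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-np.asarray(scores), kind="stable")
    keep: list[int] = []
    while order.size:
        i = int(order[0])
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = pairwise_iou(boxes[i], boxes[rest])[0]
        order = rest[ious <= iou_thresh]
    return np.asarray(keep, dtype=np.int64)


def detect(
    checkpoint: Checkpoint | SsdDetector,
    img: Radiograph,
    conf_thresh: float = 0.5,
    nms_iou: float = 0.45,
    top_k: int = 2,
    use_best_weights: bool = True,
) -> list[Detection]:
    """Run the detector on one radiograph; boxes in original coordinates.

    By default the best-validation weights are used (they equal the final
    weights when training ran without a validation split).
    """
    if isinstance(checkpoint, Checkpoint):
        model = checkpoint.build_model(best=use_best_weights)
    else:
        model = checkpoint
    from .detector_core import decode_boxes, _softmax  # local to avoid cycle at import

    model_size = model.anchors.grid.input_px
    x, t = _prepare_image(img, model_size)
    cls_logits, loc_pred = model.forward(x[None], train=False)
    conf = _softmax(cls_logits[0])[:, 1]
    decoded = decode_boxes(loc_pred[0], model.anchors.boxes, variances=model.variances)
    keep = conf >= conf_thresh
    if not keep.any():
        return []
    decoded, conf = decoded[keep], conf[keep]
    kept = nms(decoded, conf, iou_thresh=nms_iou)[:top_k]
    inv = t.inverse()
    out: list[Detection] = []
    for i in kept:
        cx, cy, w, h = decoded[i]
        side = max(w, h)  # symmetrize back to the square ROI convention
        ocx, ocy = inv.apply_point(cx, cy)
        out.append(
            Detection(
                image_id=img.source_id,
                cx=float(ocx),
                cy=float(ocy),
                side=float(side * abs(inv.scale)),
                confidence=float(conf[i]),
            )
        )
    out.sort(key=lambda d: -d.confidence)
    return out
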