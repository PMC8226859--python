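"""Simplified single-shot detector: backbone, head, matching, multibox loss.

The detector keeps only one convolutional predictor on a single g x g
feature layer (default 7 x 7 for a 224-px input) with square 1:1 anchors —
the simplification that suits radiographs containing one or two large,
non-overlapping anatomical targets.  Offsets are encoded SSD-style against
the matched anchor with variances (0.1, 0.2); training uses smooth-L1
localization plus cross-entropy classification with 3:1 hard negative
mining.

Backbones:

* ``tiny`` — a compact CPU-trainable stack of stride-2 3x3 conv blocks
  (~60k parameters) taking the 224-px input down to the 7 x 7 grid,
  implemented in NumPy with explicit backprop.
* ``resnet101_pretrained`` — the full-scale configuration; constructing it
  requires an external deep-learning framework with ImageNet weights and is
  not available here (raises NotImplementedError).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import Adam, BatchNorm2d, Conv2d, ReLU, Sequential
from .anchor_design import AnchorSet
from .evaluation import pairwise_iou

__all__ = [
    "BACKBONES",
    "MatchResult",
    "SsdDetector",
    "encode_boxes",
    "decode_boxes",
    "match_anchors",
    "multibox_loss",
]

BACKBONES = ("tiny", "resnet101_pretrained")

#: SSD box-encoding variances (center, size)
DEFAULT_VARIANCES = (0.1, 0.2)

#: channel widths of successive stride-2 blocks of the tiny backbone
TINY_CHANNELS = (8, 16, 32, 64, 64)

NEGATIVE = -1
IGNORED = -2


# ---------------------------------------------------------------------------
# box encoding
# ---------------------------------------------------------------------------


def encode_boxes(
    gt: np.ndarray, anchors: np.ndarray, variances: tuple[float, float] = DEFAULT_VARIANCES
) -> np.ndarray:
    """SSD offsets (dcx, dcy, dw, dh) of gt boxes relative to anchors.

    Both inputs are (N, 4) arrays of (cx, cy, w, h) matched row by row:
    ``dcx = (gt.cx - a.cx) / a.w / v_c`` and ``dw = log(gt.w / a.w) / v_s``.
    """
    gt = np.asarray(gt, dtype=np.float64).reshape(-1, 4)
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    if np.any(gt[:, 2:] <= 0):
        raise ValueError("ground-truth box sides must be positive")
    v_c, v_s = variances
    out = np.empty_like(gt)
    out[:, 0] = (gt[:, 0] - anchors[:, 0]) / anchors[:, 2] / v_c
    out[:, 1] = (gt[:, 1] - anchors[:, 1]) / anchors[:, 3] / v_c
    out[:, 2] = np.log(gt[:, 2] / anchors[:, 2]) / v_s
    out[:, 3] = np.log(gt[:, 3] / anchors[:, 3]) / v_s
    return out


def decode_boxes(
    offsets: np.ndarray,
    anchors: np.ndarray,
    variances: tuple[float, float] = DEFAULT_VARIANCES,
) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; returns (N, 4) (cx, cy, w, h)."""
    offsets = np.asarray(offsets, dtype=np.float64).reshape(-1, 4)
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    v_c, v_s = variances
    out = np.empty_like(offsets)
    out[:, 0] = offsets[:, 0] * v_c * anchors[:, 2] + anchors[:, 0]
    out[:, 1] = offsets[:, 1] * v_c * anchors[:, 3] + anchors[:, 1]
    out[:, 2] = np.exp(offsets[:, 2] * v_s) * anchors[:, 2]
    out[:, 3] = np.exp(offsets[:, 3] * v_s) * anchors[:, 3]
    return out


# ---------------------------------------------------------------------------
# anchor-truth matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchResult:
    """Per-anchor labels and per-gt best anchor.

    ``labels[a]`` is the matched gt index for positives, -1 for negatives,
    and -2 for ignored anchors (inside the optional ignore band: overlap too
    high to be a clean background example, too low to be positive).
    """

    labels: np.ndarray
    best_anchor_per_gt: np.ndarray
    iou_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels >= 0))


def match_anchors(
    gt_boxes: np.ndarray,
    anchor_boxes: np.ndarray,
    iou_pos: float = 0.5,
    iou_ignore: float | None = None,
) -> MatchResult:
    """Bipartite-plus-threshold matching of anchors to ground truths.

    (1) each gt's argmax-IoU anchor is positive for it (ties to the lower
    anchor index; if two gts share an argmax anchor the higher-IoU gt keeps
    it and the other takes its best remaining anchor); (2) every other
    anchor whose best IoU reaches ``iou_pos`` is positive for its argmax gt;
    (3) the rest are negative — except that with ``iou_ignore`` set, anchors
    whose best IoU lies in [iou_ignore, iou_pos) are marked ignored and
    excluded from the classification loss.
    """
    anchor_boxes = np.asarray(anchor_boxes, dtype=np.float64).reshape(-1, 4)
    n_anchors = anchor_boxes.shape[0]
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    n_gt = gt_boxes.shape[0]
    labels = np.full(n_anchors, NEGATIVE, dtype=np.int64)
    if n_gt == 0:
        return MatchResult(labels, np.empty(0, dtype=np.int64), np.zeros((n_anchors, 0)))
    mat = pairwise_iou(anchor_boxes, gt_boxes)  # (A, M)

    # rule (2): threshold assignment to each anchor's argmax gt
    best_gt = mat.argmax(axis=1)
    best_gt_iou = mat[np.arange(n_anchors), best_gt]
    if iou_ignore is not None:
        if not (0 <= iou_ignore <= iou_pos):
            raise ValueError("require 0 <= iou_ignore <= iou_pos")
        labels[best_gt_iou >= iou_ignore] = IGNORED
    labels[best_gt_iou >= iou_pos] = best_gt[best_gt_iou >= iou_pos]

    # rule (1): forced best anchor per gt, resolving shared-argmax conflicts
    # in favor of the higher-IoU gt
    best_anchor = np.full(n_gt, -1, dtype=np.int64)
    avail = mat.copy()
    order = np.argsort(-avail.max(axis=0), kind="stable")  # gts by best IoU desc
    taken: set[int] = set()
    for g in order:
        col = avail[:, g].copy()
        if taken:
            col[list(taken)] = -1.0
        a = int(col.argmax())
        best_anchor[g] = a
        taken.add(a)
        labels[a] = g
    return MatchResult(labels, best_anchor, mat)


# ---------------------------------------------------------------------------
# multibox loss
# ---------------------------------------------------------------------------


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def multibox_loss(
    cls_logits: np.ndarray,
    loc_pred: np.ndarray,
    labels: np.ndarray,
    loc_targets: np.ndarray,
    neg_pos_ratio: int = 3,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Multibox objective and its gradients w.r.t. the head outputs.

    ``cls_logits`` (B, A, 2), ``loc_pred`` (B, A, 4), ``labels`` (B, A) with
    gt index >= 0 for positives, -1 for negatives, and -2 for ignored
    anchors (excluded from every term); ``loc_targets`` (B, A, 4) encoded
    offsets (only positive rows are read).

    L = (1/N_pos) [ sum_pos smoothL1(loc_pred - loc_target)
                    + CE(positives) + CE(hardest ``neg_pos_ratio * n_pos``
                      negatives, mined per image) ].

    With no positives anywhere the loss degrades to classification only
    (all anchors background, normalized by the anchor count).
    Returns ``(loss, d_cls_logits, d_loc_pred)``.
    """
    cls_logits = np.asarray(cls_logits, dtype=np.float64)
    loc_pred = np.asarray(loc_pred, dtype=np.float64)
    labels = np.asarray(labels)
    b, a, _ = cls_logits.shape
    pos = labels >= 0
    neg = labels == NEGATIVE
    n_pos = int(pos.sum())

    probs = _softmax(cls_logits)  # (B, A, 2); class 1 = hip
    ce = -np.log(np.clip(np.where(pos, probs[:, :, 1], probs[:, :, 0]), 1e-12, None))

    selected = pos.copy()
    if n_pos > 0:
        for i in range(b):
            k = neg_pos_ratio * int(pos[i].sum())
            if k <= 0:
                continue
            neg_idx = np.flatnonzero(neg[i])
            if neg_idx.size:
                hardest = neg_idx[np.argsort(-ce[i, neg_idx], kind="stable")[:k]]
                selected[i, hardest] = True
        norm = n_pos
    else:
        selected[:] = neg
        norm = max(int(neg.sum()), 1)

    # classification term + gradient
    loss_cls = float(ce[selected].sum())
    target = np.zeros_like(probs)
    target[:, :, 1] = pos
    target[:, :, 0] = ~pos
    d_cls = np.where(selected[:, :, None], probs - target, 0.0) / norm

    # localization term + gradient (positives only)
    d_loc = np.zeros_like(loc_pred)
    loss_loc = 0.0
    if n_pos > 0:
        diff = loc_pred[pos] - np.asarray(loc_targets, dtype=np.float64)[pos]
        absd = np.abs(diff)
        loss_loc = float(np.where(absd < 1.0, 0.5 * diff**2, absd - 0.5).sum())
        d_loc[pos] = np.where(absd < 1.0, diff, np.sign(diff)) / norm

    loss = (loss_cls + loss_loc) / norm
    return loss, d_cls, d_loc


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class SsdDetector:
    """Backbone + single-feature-layer detection head.

    The backbone contracts the 1-channel model-space input to a
    ``grid_n x grid_n`` spatial map by successive stride-2 conv blocks; the
    head is one 3x3 conv emitting, per cell and per anchor scale, two class
    logits (background, hip) and four box offsets.  Output ordering matches
    :class:`~hiproi.anchor_design.AnchorSet` (row-major cells, scales
    innermost), which is asserted at construction.
    """

    def __init__(
        self,
        anchors: AnchorSet,
        backbone: str = "tiny",
        seed: int = 0,
        variances: tuple[float, float] = DEFAULT_VARIANCES,
    ) -> None:
        if backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if backbone == "resnet101_pretrained":
            raise NotImplementedError(
                "the resnet101_pretrained backbone requires an external "
                "deep-learning framework and ImageNet weights; use backbone='tiny'"
            )
        self.anchors = anchors
        self.backbone_name = backbone
        self.variances = tuple(variances)
        grid = anchors.grid
        factor = grid.input_px // grid.grid_n
        n_blocks = int(round(np.log2(factor)))
        if 2**n_blocks != factor:
            raise ValueError(
                f"input_px/grid_n must be a power of two for the tiny backbone, got {factor}"
            )
        self.k_per_cell = anchors.count // (grid.grid_n**2)
        if self.k_per_cell * grid.grid_n**2 != anchors.count:
            raise ValueError("anchor count is not a multiple of the cell count")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        channels = TINY_CHANNELS[:n_blocks]
        if n_blocks > len(TINY_CHANNELS):
            channels = channels + (TINY_CHANNELS[-1],) * (n_blocks - len(TINY_CHANNELS))
        layers = []
        c_prev = 1
        for c in channels:
            layers += [Conv2d(c_prev, c, 3, stride=2, pad=1, rng=rng),
                       BatchNorm2d(c), ReLU()]
            c_prev = c
        self.backbone = Sequential(*layers)
        # head bias: start hip logits low so early training is background-dominated
        head_bias = np.zeros(self.k_per_cell * 6, dtype=np.float32)
        head_bias.reshape(self.k_per_cell, 6)[:, 1] = -3.0
        self.head = Conv2d(c_prev, self.k_per_cell * 6, 3, stride=1, pad=1, rng=rng,
                           bias_init=head_bias)
        self._head_in_shape: tuple | None = None
        # backbone/head contract check on a dummy input
        g = grid.grid_n
        dummy = np.zeros((1, 1, grid.input_px, grid.input_px), dtype=np.float32)
        feat = self.backbone.forward(dummy, train=False)
        assert feat.shape[2:] == (g, g), f"backbone emits {feat.shape[2:]}, expected {(g, g)}"
        out = self.head.forward(feat, train=False)
        assert out.shape[1] * g * g == anchors.count * 6

    # -- forward / backward -------------------------------------------------

    def forward(
        self, x: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """(B, 1, S, S) image batch -> ((B, A, 2) logits, (B, A, 4) offsets)."""
        feat = self.backbone.forward(x.astype(np.float32), train=train)
        out = self.head.forward(feat, train=train)  # (B, K*6, g, g)
        b, _, gh, gw = out.shape
        out = out.reshape(b, self.k_per_cell, 6, gh, gw)
        out = np.moveaxis(out, (3, 4), (1, 2))  # (B, g, g, K, 6)
        out = out.reshape(b, gh * gw * self.k_per_cell, 6)
        return out[:, :, :2], out[:, :, 2:]

    def backward(self, d_cls: np.ndarray, d_loc: np.ndarray) -> None:
        b = d_cls.shape[0]
        g = self.anchors.grid.grid_n
        dout = np.concatenate([d_cls, d_loc], axis=2)  # (B, A, 6)
        dout = dout.reshape(b, g, g, self.k_per_cell, 6)
        dout = np.moveaxis(dout, (1, 2), (3, 4))  # (B, K, 6, g, g)
        dout = dout.reshape(b, self.k_per_cell * 6, g, g).astype(np.float32)
        dfeat = self.head.backward(dout)
        self.backbone.backward(dfeat)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[np.ndarray]:
        return self.backbone.params() + self.head.params()

    def grads(self) -> list[np.ndarray]:
        return self.backbone.grads() + self.head.grads()

    def make_optimizer(self, lr: float = 1e-3, weight_decay: float = 0.0) -> Adam:
        return Adam(self.params(), lr=lr, weight_decay=weight_decay)

    def buffers(self) -> list[np.ndarray]:
        return self.backbone.buffers() + self.head.buffers()

    def state_arrays(self) -> list[np.ndarray]:
        """State to persist: parameters plus normalization running stats."""
        return [p.copy() for p in self.params() + self.buffers()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        state = self.params() + self.buffers()
        if len(arrays) != len(state):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(state, arrays):
            if p.shape != a.shape:
                raise ValueError(f"parameter shape mismatch: {p.shape} vs {a.shape}")
            p[...] = a
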