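"""Box encoding, anchor matching, multibox loss, and network contracts."""

import numpy as np
import pytest

from hiproi import (
    GridSpec,
    SsdDetector,
    decode_boxes,
    design_scales,
    encode_boxes,
    generate_anchors,
    match_anchors,
    multibox_loss,
)
from hiproi.evaluation import pairwise_iou


@pytest.fixture(scope="module")
def anchors():
    return generate_anchors(design_scales(0.100, 0.314, 6))


class TestEncodeDecode:
    def test_gt_identical_to_anchor_encodes_to_zero(self):
        a = np.array([[50.0, 60.0, 32.0, 32.0]])
        assert np.allclose(encode_boxes(a, a), 0.0)

    def test_log_size_term(self):
        a = np.array([[50.0, 50.0, 32.0, 32.0]])
        gt = np.array([[50.0, 50.0, 32.0 * np.e, 32.0 * np.e]])
        enc = encode_boxes(gt, a)
        assert enc[0, 2] == pytest.approx(5.0)  # log(e) / 0.2
        assert enc[0, 3] == pytest.approx(5.0)

    def test_decode_inverts_encode_on_random_boxes(self, rng):
        n = 1000
        anchors = np.column_stack(
            [
                rng.uniform(0, 224, n),
                rng.uniform(0, 224, n),
                rng.uniform(5, 100, n),
                rng.uniform(5, 100, n),
            ]
        )
        gts = np.column_stack(
            [
                rng.uniform(0, 224, n),
                rng.uniform(0, 224, n),
                rng.uniform(5, 100, n),
                rng.uniform(5, 100, n),
            ]
        )
        back = decode_boxes(encode_boxes(gts, anchors), anchors)
        assert np.abs(back - gts).max() < 1e-6

    def test_non_positive_gt_side_rejected(self):
        a = np.array([[10.0, 10.0, 5.0, 5.0]])
        with pytest.raises(ValueError):
            encode_boxes(np.array([[10.0, 10.0, 0.0, 5.0]]), a)


def _brute_force_match(gt_boxes, anchor_boxes, iou_pos=0.5):
    """Independent application of the matching rules from an explicit IoU table."""
    mat = pairwise_iou(anchor_boxes, gt_boxes)
    n_anchors, n_gt = mat.shape
    labels = np.full(n_anchors, -1, dtype=int)
    # rule (2): threshold assignment to each anchor's argmax gt
    for a in range(n_anchors):
        g = int(np.argmax(mat[a]))
        if mat[a, g] >= iou_pos:
            labels[a] = g
    # rule (1): per-gt forced best anchor (higher-IoU gt wins conflicts)
    order = sorted(range(n_gt), key=lambda g: -mat[:, g].max())
    taken = set()
    for g in order:
        cand = sorted(range(n_anchors), key=lambda a: (-mat[a, g], a))
        a = next(a for a in cand if a not in taken)
        taken.add(a)
        labels[a] = g
    return labels


class TestMatchAnchors:
    def test_gt_equal_to_anchor(self, anchors):
        gt = anchors.boxes[[100]]
        m = match_anchors(gt, anchors.boxes)
        assert m.labels[100] == 0
        assert m.best_anchor_per_gt[0] == 100
        # every anchor overlapping at >= 0.5 is positive too
        ious = pairwise_iou(anchors.boxes, gt)[:, 0]
        assert np.all(m.labels[ious >= 0.5] == 0)

    def test_zero_truths_all_negative(self, anchors):
        m = match_anchors(np.empty((0, 4)), anchors.boxes)
        assert np.all(m.labels == -1)
        assert m.n_positive == 0

    def test_every_gt_gets_a_positive_anchor(self, anchors, rng):
        for _ in range(50):
            gts = np.column_stack(
                [
                    rng.uniform(0, 224, 2),
                    rng.uniform(0, 224, 2),
                    rng.uniform(22, 68, 2),
                    rng.uniform(22, 68, 2),
                ]
            )
            m = match_anchors(gts, anchors.boxes)
            present = set(m.labels[m.labels >= 0])
            assert present == {0, 1}

    def test_matches_brute_force_oracle(self, anchors, rng):
        for _ in range(25):
            gts = np.column_stack(
                [
                    rng.uniform(0, 224, 2),
                    rng.uniform(0, 224, 2),
                    rng.uniform(22, 68, 2),
                    rng.uniform(22, 68, 2),
                ]
            )
            m = match_anchors(gts, anchors.boxes)
            expected = _brute_force_match(gts, anchors.boxes)
            assert np.array_equal(m.labels, expected)


class TestMultiboxLoss:
    def test_perfect_predictions_drive_loss_to_zero(self):
        # 2 anchors, 1 positive: saturated logits + exact offsets
        labels = np.array([[0, -1]])
        loc_targets = np.array([[[0.3, -0.2, 0.1, 0.0], [0.0, 0.0, 0.0, 0.0]]])
        loc_pred = loc_targets.copy()
        for conf in (5.0, 15.0, 30.0):
            cls = np.array([[[-conf, conf], [conf, -conf]]])
            loss, _, _ = multibox_loss(cls, loc_pred, labels, loc_targets)
            assert loss >= 0
        assert loss < 1e-10

    def test_exact_offsets_zero_localization_term(self):
        labels = np.array([[0, -1]])
        t = np.array([[[0.5, 0.5, -1.0, 2.0], [0, 0, 0, 0]]], dtype=float)
        cls = np.zeros((1, 2, 2))
        loss_exact, _, dloc = multibox_loss(cls, t.copy(), labels, t)
        # classification-only loss: ce(pos) + ce(1 hard negative), n_pos=1
        assert loss_exact == pytest.approx(2 * np.log(2))
        assert np.allclose(dloc, 0.0)

    def test_hand_computed_two_anchor_case(self):
        # spreadsheet-style evaluation of the formula
        labels = np.array([[0, -1]])
        cls = np.array([[[0.2, 1.0], [1.5, -0.5]]])
        loc_pred = np.array([[[0.5, 0.0, 0.0, 0.0], [0, 0, 0, 0]]], dtype=float)
        loc_targets = np.array([[[2.0, 0.0, 0.0, 0.0], [0, 0, 0, 0]]], dtype=float)
        p_pos = np.exp(1.0) / (np.exp(0.2) + np.exp(1.0))
        p_neg_bg = np.exp(1.5) / (np.exp(1.5) + np.exp(-0.5))
        expected = (-np.log(p_pos)) + (-np.log(p_neg_bg)) + (1.5 - 0.5)  # n_pos=1
        loss, _, _ = multibox_loss(cls, loc_pred, labels, loc_targets)
        assert loss == pytest.approx(expected)

    def test_hard_negative_mining_selects_highest_loss_negatives(self):
        labels = np.array([[0, -1, -1, -1, -1]])
        cls = np.zeros((1, 5, 2))
        cls[0, 1] = [0.0, 3.0]   # hardest negative (confident hip)
        cls[0, 2] = [0.0, 1.0]
        cls[0, 3] = [2.0, -2.0]  # easy negative
        cls[0, 4] = [3.0, -3.0]  # easiest negative
        t = np.zeros((1, 5, 4))
        _, d_cls, _ = multibox_loss(cls, t, labels, t, neg_pos_ratio=2)
        touched = np.flatnonzero(np.abs(d_cls[0]).sum(axis=1) > 0)
        assert touched.tolist() == [0, 1, 2]  # positive + 2 hardest negatives

    def test_no_positives_falls_back_to_classification(self):
        labels = np.full((1, 4), -1)
        cls = np.zeros((1, 4, 2))
        t = np.zeros((1, 4, 4))
        loss, d_cls, d_loc = multibox_loss(cls, t, labels, t)
        assert loss == pytest.approx(np.log(2))
        assert np.allclose(d_loc, 0.0)
        assert np.abs(d_cls).sum() > 0

    def test_gradients_match_finite_differences(self, rng):
        labels = np.array([[1, -1, 0, -1]])
        cls = rng.normal(size=(1, 4, 2))
        loc_pred = rng.normal(size=(1, 4, 4))
        loc_t = rng.normal(size=(1, 4, 4))
        loss, d_cls, d_loc = multibox_loss(cls, loc_pred, labels, loc_t)
        eps = 1e-6
        for arr, grad in ((cls, d_cls), (loc_pred, d_loc)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(arr.size):
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = multibox_loss(cls, loc_pred, labels, loc_t)
                arr[idx] = orig - eps
                lm, _, _ = multibox_loss(cls, loc_pred, labels, loc_t)
                arr[idx] = orig
                assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)
                it.iternext()


class TestSsdDetector:
    def test_backbone_and_head_contract(self, anchors):
        model = SsdDetector(anchors, seed=0)
        x = np.zeros((2, 1, 224, 224), dtype=np.float32)
        cls, loc = model.forward(x, train=False)
        assert cls.shape == (2, 294, 2)
        assert loc.shape == (2, 294, 4)

    def test_smaller_input_grid_contract(self):
        grid = GridSpec(input_px=112, grid_n=7)
        a = generate_anchors(design_scales(0.100, 0.314, 6, grid), grid)
        model = SsdDetector(a, seed=0)
        cls, loc = model.forward(np.zeros((1, 1, 112, 112), dtype=np.float32),
                                 train=False)
        assert cls.shape == (1, 294, 2)

    def test_resnet_backbone_unavailable(self, anchors):
        with pytest.raises(NotImplementedError):
            SsdDetector(anchors, backbone="resnet101_pretrained")

    def test_head_output_anchor_ordering(self, anchors, rng):
        # perturbing the input pixels under one grid cell must only move the
        # predictions of anchors in a neighborhood of that cell (locality of
        # the head), and the flattened ordering must follow AnchorSet records
        model = SsdDetector(anchors, seed=1)
        x = rng.normal(size=(1, 1, 224, 224)).astype(np.float32)
        cls0, _ = model.forward(x, train=False)
        x2 = x.copy()
        x2[0, 0, :32, :32] += 10.0  # cell (0, 0)
        cls1, _ = model.forward(x2, train=False)
        delta = np.abs(cls1 - cls0).sum(axis=2)[0]  # per anchor
        per_anchor_cell = [(r[0], r[1]) for r in anchors.records]
        moved = {per_anchor_cell[i] for i in np.flatnonzero(delta > 1e-4)}
        assert (0, 0) in moved
        assert all(i <= 4 and j <= 4 for i, j in moved)  # receptive-field bound

    def test_network_gradients_match_finite_differences(self, rng):
        # end-to-end gradient check on a tiny grid via the multibox loss
        grid = GridSpec(input_px=8, grid_n=2)
        from hiproi.anchor_design import ScaleSet

        a = generate_anchors(ScaleSet((1.0, 1.5)), grid)
        model = SsdDetector(a, seed=3)
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        labels = np.array([[0, -1, -1, 1, -1, -1, -1, -1]])
        loc_t = rng.normal(size=(1, 8, 4)) * 0.5

        def loss_value():
            cls, loc = model.forward(x, train=True)
            return multibox_loss(cls, loc, labels, loc_t)

        loss, d_cls, d_loc = loss_value()
        model.backward(d_cls, d_loc)
        grads = [g.copy() for g in model.grads()]
        eps, checked = 1e-3, 0
        for p, g in zip(model.params(), grads):
            flat = p.reshape(-1)
            for k in range(0, flat.size, max(flat.size // 5, 1)):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _, _ = loss_value()
                flat[k] = orig - eps
                lm, _, _ = loss_value()
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[k] == pytest.approx(num, abs=5e-3)
                checked += 1
        assert checked >= 20
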