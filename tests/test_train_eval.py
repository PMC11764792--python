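"""Loss, learning-rate schedule, confusion-matrix metrics, training loop, Grad-CAM."""

import math

import numpy as np
import pytest

import riceseg.nn as nn
from riceseg.model import build_model
from riceseg.train import (ConfusionMatrix, TrainConfig, accumulate_confusion,
                           combined_loss, evaluate, grad_cam, load_checkpoint,
                           lr_at, metrics, save_checkpoint, train)


def brute_force_metrics(pred, true, k=4):
    """Independent per-pixel implementation of PA/CPA/IoU/F1."""
    pred, true = np.asarray(pred).ravel(), np.asarray(true).ravel()
    pa = float((pred == true).mean())
    cpa, iou, f1 = [], [], []
    for c in range(k):
        tp = int(((pred == c) & (true == c)).sum())
        fp = int(((pred == c) & (true != c)).sum())
        fn = int(((pred != c) & (true == c)).sum())
        if tp + fp + fn == 0:
            cpa.append(1.0), iou.append(1.0), f1.append(1.0)
            continue
        cpa.append(tp / (tp + fp) if tp + fp else 0.0)
        iou.append(tp / (tp + fp + fn))
        f1.append(2 * tp / (2 * tp + fp + fn))
    return pa, cpa, iou, f1


class TestCombinedLoss:
    def test_uniform_logits_cross_entropy_is_ln4(self):
        logits = nn.Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32), requires_grad=True)
        mask = np.random.default_rng(0).integers(0, 4, size=(1, 4, 4))
        loss = combined_loss(logits, mask)
        # the CE term is exactly ln 4; the Dice term is computed separately below
        p = np.full((1, 4, 4, 4), 0.25)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, mask[:, None], 1.0, axis=1)
        inter = (p * onehot).sum(axis=(0, 2, 3))
        dice = 1 - np.mean((2 * inter + 1) / (p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + 1))
        assert abs(loss.item() - (math.log(4) + dice)) < 1e-6

    def test_confident_correct_logits_give_near_zero_loss(self):
        mask = np.random.default_rng(1).integers(0, 4, size=(1, 8, 8))
        logits = np.full((1, 4, 8, 8), -50.0, dtype=np.float32)
        np.put_along_axis(logits, mask[:, None], 50.0, axis=1)
        assert combined_loss(nn.Tensor(logits), mask).item() < 0.01

    def test_matches_hand_evaluation_on_2x2(self, rng):
        """Independent numpy evaluation of CE + soft Dice (smoothing 1)."""
        logits = rng.normal(size=(1, 4, 2, 2))
        mask = np.array([[[0, 1], [2, 3]]])
        got = combined_loss(nn.Tensor(logits), mask).item()
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        ce = -np.mean([np.log(p[0, mask[0, i, j], i, j]) for i in range(2) for j in range(2)])
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, mask[:, None], 1.0, axis=1)
        inter = (p * onehot).sum(axis=(0, 2, 3))
        dice = 1 - np.mean((2 * inter + 1) / (p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + 1))
        assert abs(got - (ce + dice)) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask shape"):
            combined_loss(nn.Tensor(np.zeros((1, 4, 4, 4))), np.zeros((1, 5, 5), dtype=int))


class TestLrSchedule:
    def test_endpoints_exact(self):
        cfg = TrainConfig()
        assert lr_at(0, 1000, cfg) == pytest.approx(1e-4, abs=1e-12)
        assert lr_at(1000, 1000, cfg) == pytest.approx(1e-6, abs=1e-12)

    def test_cosine_midpoint(self):
        assert lr_at(500, 1000, TrainConfig()) == pytest.approx(5.05e-5, rel=1e-9)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig()
        vals = [lr_at(s, 200, cfg) for s in range(201)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            lr_at(11, 10, TrainConfig())


class TestConfusionMatrix:
    def test_perfect_prediction_hits_diagonal(self):
        m = np.random.default_rng(0).integers(0, 4, size=(10, 10))
        cm = accumulate_confusion(m, m)
        assert np.trace(cm.counts) == 100 and cm.total == 100

    def test_single_confusion_cell(self):
        cm = accumulate_confusion(np.full((10, 10), 1), np.full((10, 10), 2))
        assert cm.counts[2, 1] == 100 and cm.counts.sum() == 100

    def test_matches_nested_loop_tally(self, rng):
        pred = rng.integers(0, 4, size=(4, 4))
        true = rng.integers(0, 4, size=(4, 4))
        cm = accumulate_confusion(pred, true)
        ref = np.zeros((4, 4), dtype=np.int64)
        for i in range(4):
            for j in range(4):
                ref[true[i, j], pred[i, j]] += 1
        assert np.array_equal(cm.counts, ref)

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            accumulate_confusion(np.array([5]), np.array([0]))


class TestMetrics:
    def test_one_vs_rest_hand_case(self):
        # TP=8, FP=2, FN=10, TN=80 for the foreground of a 2-class problem
        cm = ConfusionMatrix(2)
        cm.counts = np.array([[80, 2], [10, 8]], dtype=np.int64)
        rep = metrics(cm)
        assert rep.pa == pytest.approx(0.88)
        assert rep.cpa[1] == pytest.approx(0.8)
        assert rep.iou[1] == pytest.approx(0.4)
        assert rep.f1_per_class[1] == pytest.approx(16 / 28)

    def test_perfect_prediction_scores_one(self):
        m = np.random.default_rng(0).integers(0, 4, size=(16, 16))
        rep = metrics(accumulate_confusion(m, m))
        assert rep.pa == rep.miou_all == rep.f1 == 1.0
        assert rep.cpa == (1.0,) * 4

    def test_empty_class_convention(self):
        pred = np.zeros((4, 4), dtype=int)
        rep = metrics(accumulate_confusion(pred, pred))
        assert rep.empty_classes == (1, 2, 3)
        assert rep.iou[1] == 1.0 and rep.miou_all == 1.0

    def test_agrees_with_brute_force_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pred = rng.integers(0, 4, size=(16, 16))
            true = rng.integers(0, 4, size=(16, 16))
            rep = metrics(accumulate_confusion(pred, true))
            pa, cpa, iou, f1 = brute_force_metrics(pred, true)
            assert rep.pa == pa
            assert np.allclose(rep.cpa, cpa, atol=1e-12)
            assert np.allclose(rep.iou, iou, atol=1e-12)
            assert np.allclose(rep.f1_per_class, f1, atol=1e-12)

    def test_pa_invariant_under_simultaneous_relabeling(self, rng):
        pred = rng.integers(0, 4, size=(8, 8))
        true = rng.integers(0, 4, size=(8, 8))
        perm = np.array([2, 3, 0, 1])
        a = metrics(accumulate_confusion(pred, true)).pa
        b = metrics(accumulate_confusion(perm[pred], perm[true])).pa
        assert a == b

    def test_per_class_iou_never_exceeds_cpa(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 4, size=(12, 12))
            true = rng.integers(0, 4, size=(12, 12))
            rep = metrics(accumulate_confusion(pred, true))
            assert all(i <= c + 1e-12 for i, c in zip(rep.iou, rep.cpa))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix())


class TestTrainLoop:
    def test_identical_seeds_identical_first_epoch_loss(self, tiny_dataset):
        losses = []
        for _ in range(2):
            model = build_model(variant="baseline", input_size=64, init_seed=3)
            cfg = TrainConfig(input_size=64, batch_size=8, epochs=1, seed=3)
            log = train(model, (tiny_dataset["x"], tiny_dataset["y"]), None, cfg)
            losses.append(log.rows[0]["loss"])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_zero_epochs_returns_initial_model_empty_log(self, tiny_dataset):
        model = build_model(variant="baseline", input_size=64, init_seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        log = train(model, (tiny_dataset["x"], tiny_dataset["y"]), None,
                    TrainConfig(input_size=64, epochs=0))
        assert log.rows == []
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_loss_decreases_early(self, tiny_dataset):
        model = build_model(variant="baseline", input_size=64, init_seed=1)
        cfg = TrainConfig(input_size=64, batch_size=8, epochs=6, seed=1)
        log = train(model, (tiny_dataset["x"], tiny_dataset["y"]), None, cfg)
        losses = [r["loss"] for r in log.rows]
        assert losses[-1] < losses[0]

    def test_empty_dataset_rejected(self):
        model = build_model(variant="baseline", input_size=64)
        with pytest.raises(ValueError, match="empty training set"):
            train(model, (np.zeros((0, 3, 64, 64)), np.zeros((0, 64, 64))), None,
                  TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, tmp_path, tiny_dataset):
        model = build_model(variant="p_fpn", input_size=64, init_seed=2)
        save_checkpoint(tmp_path / "ck.npz", model, TrainConfig(input_size=64))
        loaded, meta = load_checkpoint(tmp_path / "ck.npz")
        assert meta["model"]["variant"] == "p_fpn"
        x = tiny_dataset["x"][:1]
        assert np.array_equal(model.predict(x), loaded.predict(x))


@pytest.fixture(scope="module")
def cam_model():
    return build_model(variant="full", input_size=64, init_seed=0)


class TestGradCam:
    def test_heatmap_in_unit_interval(self, cam_model, tiny_dataset):
        heat = grad_cam(cam_model, tiny_dataset["x"][0], class_k=1)
        assert heat.shape == (64, 64)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_zero_activations_give_zero_heatmap(self, tiny_dataset):
        model = build_model(variant="baseline", input_size=64, init_seed=0)
        model.head.fuse.weight.data[...] = 0.0
        model.head.fuse.bias.data[...] = 0.0
        heat = grad_cam(model, tiny_dataset["x"][0], class_k=0, layer="head.fuse")
        assert np.all(heat == 0.0)

    def test_matches_manual_weighted_sum(self, cam_model, tiny_dataset):
        """Recompute the CAM from independently captured activations/gradients."""
        from riceseg.nn import functional as F

        model = cam_model
        target = model.head.fuse
        store = {}
        orig = target.forward

        def capture(*a, **k):
            out = orig(*a, **k)
            out.retain_grad = True
            store["act"] = out
            return out

        target.forward = capture
        try:
            model.eval()
            logits = model(nn.Tensor(tiny_dataset["x"][:1]), upsample_to_input=False)
            F.sum_all(F.narrow(logits, 1, 2, 1)).backward()
        finally:
            target.forward = orig
            model.train()
        act = store["act"]
        w = act.grad.mean(axis=(2, 3), keepdims=True)
        cam = np.maximum((w * act.data).sum(axis=1), 0)[0]
        cam = (cam - cam.min()) / (cam.max() - cam.min())
        with nn.no_grad():
            ref = F.resize_bilinear(nn.Tensor(cam[None, None].astype(np.float32)), 64, 64).data[0, 0]
        got = grad_cam(model, tiny_dataset["x"][0], class_k=2, layer="head.fuse")
        assert np.allclose(got, np.clip(ref, 0, 1), atol=1e-5)

    def test_unknown_layer_lists_available(self, cam_model, tiny_dataset):
        with pytest.raises(KeyError, match="head.fuse"):
            grad_cam(cam_model, tiny_dataset["x"][0], 0, layer="nonexistent")

    def test_invalid_class_rejected(self, cam_model, tiny_dataset):
        with pytest.raises(ValueError, match="class"):
            grad_cam(cam_model, tiny_dataset["x"][0], 9)


def test_evaluate_on_predictions(tiny_dataset):
    model = build_model(variant="baseline", input_size=64, init_seed=0)
    rep = evaluate(model, tiny_dataset["x"], tiny_dataset["y"])
    assert 0.0 <= rep.pa <= 1.0 and 0.0 <= rep.miou_all <= 1.0
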