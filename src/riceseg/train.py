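"""Training recipe, segmentation metrics and Grad-CAM diagnostics.

The loss is cross-entropy plus soft Dice (unit weights, smoothing 1.0);
the optimizer is Adam (lr 1e-4, betas 0.9/0.999, weight decay 0.01) with
cosine decay of the learning rate to 0.01x its initial value.  All
metrics derive from a 4x4 pixel confusion matrix via one-vs-rest
marginalization:

    PA   = trace / total                       (micro pixel accuracy)
    CPA  = TP / (TP + FP)                      (per class)
    IoU  = TP / (TP + FP + FN), mIoU = mean over classes
    F1   = 2 TP / (2 TP + FP + FN), macro-averaged

Classes absent from both the reference and the prediction score 1.0 and
are flagged, so empty classes never divide by zero.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import NUM_CLASSES, corpus_statistics, normalize_images
from .model import ModelConfig, RiceSegFormer
from .nn import functional as F
from .nn.optim import Adam, cosine_lr
from .nn.tensor import Tensor

__all__ = [
    "TrainConfig", "ConfusionMatrix", "MetricReport", "combined_loss",
    "lr_at", "accumulate_confusion", "metrics", "evaluate", "train",
    "TrainLog", "grad_cam", "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    input_size: int = 512
    batch_size: int = 8
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    min_lr_ratio: float = 0.01
    dropout: float = 0.1
    epochs: int = 800
    augment_prob: float = 0.5
    early_stop_pa: float | None = None  # stop once validation PA exceeds this
    seed: int = 0


# -- loss ---------------------------------------------------------------------

def combined_loss(logits: Tensor, mask: np.ndarray, dice_smooth: float = 1.0) -> Tensor:
    """Cross-entropy + soft Dice on (B, K, H, W) logits and (B, H, W) labels."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    b, k, h, w = logits.shape
    if mask.shape != (b, h, w):
        raise ValueError(f"mask shape {mask.shape} does not match logits {(b, h, w)}")
    onehot = np.zeros((b, k, h, w), dtype=logits.data.dtype)
    np.put_along_axis(onehot, mask[:, None], 1.0, axis=1)

    logp = F.log_softmax(logits, axis=1)
    ce = F.scale(F.sum_all(F.mul(logp, nn.Tensor(onehot))), -1.0 / (b * h * w))

    p = F.exp(logp)
    inter = F.sum_axes(F.mul(p, nn.Tensor(onehot)), (0, 2, 3))
    psum = F.sum_axes(p, (0, 2, 3))
    tsum = onehot.sum(axis=(0, 2, 3))
    dice_per_class = F.div(
        F.scale(inter, 2.0) + dice_smooth,
        psum + nn.Tensor(tsum + dice_smooth),
    )
    dice = 1.0 + F.scale(F.mean_all(dice_per_class), -1.0)
    return ce + dice


def lr_at(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Cosine-decayed learning rate at ``step`` of ``total_steps``."""
    return cosine_lr(step, total_steps, cfg.lr, cfg.min_lr_ratio)


# -- confusion & metrics ------------------------------------------------------

class ConfusionMatrix:
    """K x K pixel-count table; entry (i, j) = true class i predicted as j."""

    def __init__(self, num_classes: int = NUM_CLASSES):
        self.k = num_classes
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    def update(self, pred: np.ndarray, true: np.ndarray) -> "ConfusionMatrix":
        pred = np.asarray(pred).ravel()
        true = np.asarray(true).ravel()
        if pred.shape != true.shape:
            raise ValueError("prediction and reference shapes differ")
        for name, arr in (("prediction", pred), ("reference", true)):
            if arr.min() < 0 or arr.max() >= self.k:
                raise ValueError(f"{name} contains classes outside 0..{self.k - 1}")
        self.counts += np.bincount(
            true * self.k + pred, minlength=self.k * self.k
        ).reshape(self.k, self.k)
        return self

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``c``."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum()) - tp
        fn = int(self.counts[c, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def accumulate_confusion(pred: np.ndarray, true: np.ndarray,
                         cm: ConfusionMatrix | None = None) -> ConfusionMatrix:
    cm = cm or ConfusionMatrix()
    return cm.update(pred, true)


@dataclass
class MetricReport:
    pa: float
    cpa: tuple
    iou: tuple
    f1_per_class: tuple
    miou_all: float
    miou_fg: float
    f1: float
    empty_classes: tuple = ()

    # per-class pixel-accuracy aliases: grains / stems / branches
    @property
    def gpa(self) -> float:
        return self.cpa[1]

    @property
    def spa(self) -> float:
        return self.cpa[2]

    @property
    def bpa(self) -> float:
        return self.cpa[3]

    @property
    def miou(self) -> float:
        return self.miou_all

    def as_percent(self) -> dict:
        return {
            "PA": 100 * self.pa, "GPA": 100 * self.gpa, "SPA": 100 * self.spa,
            "BPA": 100 * self.bpa, "mIoU": 100 * self.miou_all,
            "mIoU_fg": 100 * self.miou_fg, "F1": 100 * self.f1,
        }


def _safe_ratio(num: float, den: float, empty: bool) -> float:
    if den == 0:
        return 1.0 if empty else 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.k
    cpa, iou, f1c, empties = [], [], [], []
    for c in range(k):
        tp, fp, fn, tn = cm.one_vs_rest(c)
        empty = (tp + fp + fn) == 0  # class absent from both reference and prediction
        if empty:
            empties.append(c)
        cpa.append(_safe_ratio(tp, tp + fp, empty))
        iou.append(_safe_ratio(tp, tp + fp + fn, empty))
        f1c.append(_safe_ratio(2 * tp, 2 * tp + fp + fn, empty))
    return MetricReport(
        pa=float(np.trace(cm.counts)) / cm.total,
        cpa=tuple(cpa),
        iou=tuple(iou),
        f1_per_class=tuple(f1c),
        miou_all=float(np.mean(iou)),
        miou_fg=float(np.mean(iou[1:])),
        f1=float(np.mean(f1c)),
        empty_classes=tuple(empties),
    )


def evaluate(model: RiceSegFormer, images: np.ndarray, masks: np.ndarray,
             batch_size: int = 8) -> MetricReport:
    """Run the model over normalized image batches and score all pixels."""
    cm = ConfusionMatrix()
    model.eval()
    for i in range(0, len(images), batch_size):
        pred = model.predict(images[i:i + batch_size])
        cm.update(pred, masks[i:i + batch_size])
    model.train()
    return metrics(cm)


# -- training loop ------------------------------------------------------------

@dataclass
class TrainLog:
    rows: list = field(default_factory=list)  # dicts: epoch, lr, loss, PA, ...
    best_miou: float = -1.0
    best_epoch: int = -1
    best_state: dict | None = None

    def to_csv(self, path: str | Path) -> None:
        if not self.rows:
            Path(path).write_text("")
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.rows[0]))
            writer.writeheader()
            writer.writerows(self.rows)


def train(model: RiceSegFormer, train_data, val_data, cfg: TrainConfig,
          verbose: bool = False) -> TrainLog:
    """Seeded training loop with per-epoch validation.

    ``train_data`` / ``val_data`` are (images, masks) pairs of normalized
    float32 batches (B, 3, H, W) and int label maps (B, H, W).  The model
    state with the best validation mIoU is kept in the returned log.
    """
    x_train, y_train = train_data
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=(cfg.beta1, cfg.beta2),
               weight_decay=cfg.weight_decay)
    n = len(x_train)
    steps_per_epoch = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    log = TrainLog()
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            opt.lr = lr_at(step, total_steps, cfg)
            xb = nn.Tensor(np.ascontiguousarray(x_train[idx]))
            logits = model(xb)
            loss = combined_loss(logits, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
            step += 1
        row = {"epoch": epoch, "lr": opt.lr, "loss": epoch_loss / n}
        if val_data is not None and len(val_data[0]):
            rep = evaluate(model, val_data[0], val_data[1], cfg.batch_size)
            row.update({"PA": rep.pa, "GPA": rep.gpa, "SPA": rep.spa,
                        "BPA": rep.bpa, "mIoU": rep.miou_all, "F1": rep.f1})
            if rep.miou_all > log.best_miou:
                log.best_miou = rep.miou_all
                log.best_epoch = epoch
                log.best_state = model.state_dict()
        log.rows.append(row)
        if verbose:
            print(", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in row.items()))
        if (cfg.early_stop_pa is not None and "PA" in row
                and row["PA"] >= cfg.early_stop_pa):
            break
    return log


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(path: str | Path, model: RiceSegFormer,
                    train_cfg: TrainConfig | None = None) -> None:
    """Weights + embedded model/training configuration in one .npz file."""
    meta = {"model": model.cfg.to_dict()}
    if train_cfg is not None:
        meta["train"] = train_cfg.__dict__
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[RiceSegFormer, dict]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    model = RiceSegFormer(ModelConfig.from_dict(meta["model"]))
    model.load_state_dict(state)
    return model, meta


# -- Grad-CAM -----------------------------------------------------------------

def grad_cam(model: RiceSegFormer, image: np.ndarray, class_k: int,
             layer: str = "head.fuse") -> np.ndarray:
    """Class activation heatmap in [0, 1] at the input resolution.

    Channel weights are the spatial mean of d(score_k)/d(activation) at
    the named layer (default: the final fusion convolution); the heatmap
    is the rectified weighted activation sum, min-max normalized and
    bilinearly upsampled.  ``score_k`` is the sum of class-k logits.
    """
    if not 0 <= class_k < model.cfg.num_classes:
        raise ValueError(f"class {class_k} outside 0..{model.cfg.num_classes - 1}")
    modules = dict(model.named_modules())
    if layer not in modules:
        leaves = sorted(k for k, m in modules.items() if k and not any(True for _ in m._children()))
        raise KeyError(f"unknown layer {layer!r}; available layers: {leaves}")
    target = modules[layer]

    captured: list[Tensor] = []
    original_forward = target.forward

    def capture(*args, **kwargs):
        out = original_forward(*args, **kwargs)
        out.retain_grad = True
        captured.append(out)
        return out

    target.forward = capture
    try:
        model.eval()
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        logits = model(nn.Tensor(x), upsample_to_input=False)
        score = F.sum_all(F.narrow(logits, 1, class_k, 1))
        score.backward()
    finally:
        target.forward = original_forward
        model.train()
    act = captured[-1]
    if act.grad is None:
        raise RuntimeError(f"layer {layer!r} received no gradient")
    weights = act.grad.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * act.data).sum(axis=1), 0.0)[0]
    span = cam.max() - cam.min()
    if span > 0:
        cam = (cam - cam.min()) / span
    else:
        cam = np.zeros_like(cam)
    h, w = x.shape[-2:]
    with nn.no_grad():
        out = F.resize_bilinear(nn.Tensor(cam[None, None].astype(np.float32)), h, w)
    return np.clip(out.data[0, 0], 0.0, 1.0)
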