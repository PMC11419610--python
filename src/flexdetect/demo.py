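"""Miniature end-to-end detector and the loss-robustness experiment.

The detector here is deliberately small: a three-stage convolutional
backbone on 64 x 64 inputs, an optional residual deformable block in the
deepest stage, optional BiC fusion of the two finest pyramid levels and an
optional SlimCSPSPPF on the deepest level, SimAM attention before the head,
and a single-scale anchor-free head (each 8 x 8 grid cell predicts one box,
objectness and class scores).  It exists to smoke-test how the blocks and
the box losses interact end to end on synthetic scenes — it is not a
full-scale detector.

:func:`box_regression_experiment` is the isolated study of loss robustness
to corrupted annotations: a small shared network refines random anchor boxes
toward labels of which a seeded fraction is heavily jittered, and the final
median IoU error is measured against the *clean* targets.  A shared
predictor is essential — with independent per-anchor parameters the choice
of loss would only rescale per-sample steps and corruption could not
propagate between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attention import SimAM
from .autograd import Tensor, maximum, stack
from .deformable import DCNBlock
from .fusion import BiC, SlimCSPSPPF
from .io_formats import Box
from .losses import LossState, box_loss, iou
from .metrics import box_iou, evaluate
from .nn import CBL, Adam, Conv2d, Module
from .synthetic import SceneSpec, generate_scene, perturb_labels

__all__ = ["DemoConfig", "DemoDetector", "train_demo", "nms",
           "box_regression_experiment"]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class DemoConfig:
    """Demo training configuration (optimizer defaults follow the full-scale
    recipe where they make sense at this size: Adam, lr0 = 0.01)."""

    img_size: int = 64
    n_classes: int = 4
    channels: tuple[int, int, int] = (8, 16, 16)
    use_dcn: bool = True
    use_simam: bool = True
    use_bic: bool = False
    use_sppf: bool = False
    box_loss: str = "ciou"
    lr0: float = 0.01
    batch_size: int = 8
    steps: int = 250
    n_train: int = 64
    n_val: int = 24
    label_noise: float = 0.0
    conf_thresh: float = 0.10
    nms_iou: float = 0.45
    seed: int = 0


class DemoDetector(Module):
    """Single-scale anchor-free detector on 64 x 64 RGB inputs.

    Output grid is ``img_size / 8`` per side; each cell predicts
    ``(tx, ty, tw, th, obj, class logits...)``.  Centers decode to
    ``(cell + sigmoid(t)) * 8`` pixels, sizes to ``sigmoid(t) * img_size``.
    """

    STRIDE = 8

    def __init__(self, cfg: DemoConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.channels
        self.cfg = cfg
        self.stem = CBL(3, c1, stride=2, rng=rng)            # 64 -> 32
        self.stage2 = CBL(c1, c2, stride=2, rng=rng)         # 32 -> 16
        if cfg.use_dcn:
            self.stage3 = DCNBlock(c2, c3, stride=2, rng=rng)  # 16 -> 8
        else:
            self.stage3 = CBL(c2, c3, stride=2, rng=rng)
        self.sppf = SlimCSPSPPF(c3, c3, rng=rng) if cfg.use_sppf else None
        if cfg.use_bic:
            self.bic = BiC(c1, c2, c3, c2, rng=rng)
            self.bic_down = CBL(c2, c3, stride=2, rng=rng)
        else:
            self.bic = None
        self.attn = SimAM() if cfg.use_simam else None
        self.head = Conv2d(c3, 5 + cfg.n_classes, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        f1 = self.stem(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        if self.sppf is not None:
            f3 = self.sppf(f3)
        if self.bic is not None:
            f3 = f3 + self.bic_down(self.bic(f1, f2, f3))
        if self.attn is not None:
            f3 = self.attn(f3)
        return self.head(f3)  # (N, 5 + K, G, G)

    # -- decoding -----------------------------------------------------------
    def decode(self, raw: np.ndarray) -> list[list[Box]]:
        """Raw head output -> per-image normalized candidate boxes."""
        s = self.cfg.img_size
        g = s // self.STRIDE
        out: list[list[Box]] = []
        for sample in raw:
            boxes: list[Box] = []
            obj = _sigmoid(sample[4])
            cls_logits = sample[5:]
            cls_prob = _softmax(cls_logits, axis=0)
            for i in range(g):
                for j in range(g):
                    conf = float(obj[i, j] * cls_prob[:, i, j].max())
                    if conf < self.cfg.conf_thresh:
                        continue
                    cx = (j + _sigmoid(sample[0, i, j])) * self.STRIDE / s
                    cy = (i + _sigmoid(sample[1, i, j])) * self.STRIDE / s
                    w = max(_sigmoid(sample[2, i, j]), 1e-3)
                    h = max(_sigmoid(sample[3, i, j]), 1e-3)
                    cls = int(cls_prob[:, i, j].argmax())
                    boxes.append(Box(cls, float(np.clip(cx, 0, 1)),
                                     float(np.clip(cy, 0, 1)),
                                     float(w), float(h), conf))
            out.append(nms(boxes, self.cfg.nms_iou))
        return out

    def predict(self, images: np.ndarray) -> list[list[Box]]:
        """Images (N, H, W, 3) uint8 -> per-image detections after NMS."""
        self.eval()
        x = Tensor(_to_input(images))
        raw = self.forward(x).data
        self.train()
        return self.decode(raw)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _softmax(z, axis=0):
    m = z.max(axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)


def _to_input(images: np.ndarray) -> np.ndarray:
    return np.asarray(images, dtype=float).transpose(0, 3, 1, 2) / 255.0


def nms(boxes: list[Box], iou_thresh: float = 0.45) -> list[Box]:
    """Minimal greedy non-maximum suppression (per class)."""
    kept: list[Box] = []
    for b in sorted(boxes, key=lambda b: -(b.conf or 0.0)):
        if all(b.cls != k.cls or box_iou(b, k) < iou_thresh for k in kept):
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    # max(z,0) - z*t + log(1 + exp(-|z|)) : numerically stable
    return (maximum(z, 0.0) - z * target
            + (1.0 + (-z.abs()).exp()).log()).mean()


def detection_loss(model: DemoDetector, raw: Tensor,
                   gt: Sequence[Sequence[Box]],
                   state: LossState) -> tuple[Tensor, dict]:
    """Objectness BCE + class CE + box loss at positive cells."""
    cfg = model.cfg
    g = cfg.img_size // model.STRIDE
    n = len(gt)
    obj_t = np.zeros((n, g, g))
    pos: list[tuple[int, int, int, Box]] = []
    for b_idx, boxes in enumerate(gt):
        seen: dict[tuple[int, int], Box] = {}
        for b in boxes:
            px, py = b.cx * cfg.img_size, b.cy * cfg.img_size
            j = min(int(px // model.STRIDE), g - 1)
            i = min(int(py // model.STRIDE), g - 1)
            seen[(i, j)] = b  # two centers in one cell: last one wins
        for (i, j), b in seen.items():
            obj_t[b_idx, i, j] = 1.0
            pos.append((b_idx, i, j, b))

    loss_obj = _bce_with_logits(raw[:, 4], obj_t)
    parts = {"obj": float(loss_obj.data)}
    if not pos:
        return loss_obj, parts

    bidx = np.array([p[0] for p in pos])
    ii = np.array([p[1] for p in pos])
    jj = np.array([p[2] for p in pos])
    tgt_cls = np.array([p[3].cls for p in pos])
    tgt_box = np.array([[p[3].cx * cfg.img_size, p[3].cy * cfg.img_size,
                         p[3].w * cfg.img_size, p[3].h * cfg.img_size]
                        for p in pos])

    sel = raw[bidx, :, ii, jj]  # (P, 5 + K)
    pred_cx = (jj + sel[:, 0].sigmoid()) * model.STRIDE
    pred_cy = (ii + sel[:, 1].sigmoid()) * model.STRIDE
    pred_w = sel[:, 2].sigmoid() * cfg.img_size + 1e-3
    pred_h = sel[:, 3].sigmoid() * cfg.img_size + 1e-3
    pred_box = stack([pred_cx, pred_cy, pred_w, pred_h], axis=1)

    loss_box = box_loss(cfg.box_loss, pred_box, Tensor(tgt_box),
                        state if cfg.box_loss == "wiou3" else None).mean()

    logits = sel[:, 5:]  # (P, K)
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    picked = logits[np.arange(len(pos)), tgt_cls]
    loss_cls = (lse.reshape(len(pos)) - picked).mean()

    total = loss_obj + loss_box + 0.5 * loss_cls
    parts.update(box=float(loss_box.data), cls=float(loss_cls.data))
    return total, parts


@dataclass
class TrainResult:
    map50_trained: float
    map50_untrained: float
    losses: list[float] = field(repr=False, default_factory=list)
    report: object = None


def _scene_batch(spec: SceneSpec, seeds: Sequence[int], label_noise: float):
    imgs, gts = [], []
    for s in seeds:
        img, boxes = generate_scene(spec, seed=int(s))
        if label_noise > 0:
            boxes, _ = perturb_labels(boxes, label_noise, 0.4, seed=int(s) + 13)
        imgs.append(img)
        gts.append(boxes)
    return np.stack(imgs), gts


def train_demo(cfg: DemoConfig) -> TrainResult:
    """Train the miniature detector on synthetic scenes; report mAP50.

    Evaluation labels of the held-out split are always clean; label noise
    (``cfg.label_noise``) applies to training labels only.  Divergence (a
    non-finite loss) aborts with diagnostics.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = SceneSpec(height=cfg.img_size, width=cfg.img_size,
                     min_objects=1, max_objects=2)
    train_seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_train)
    val_seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_val)
    val_imgs, val_gts = _scene_batch(spec, val_seeds, 0.0)

    model = DemoDetector(cfg, rng=np.random.default_rng(cfg.seed + 1))
    map_untrained = _eval_map(model, val_imgs, val_gts, cfg.n_classes)

    if cfg.steps > 0:
        opt = Adam(model.parameters(), lr=cfg.lr0)
        state = LossState()
        losses = []
        for step in range(cfg.steps):
            batch = rng.choice(train_seeds, size=cfg.batch_size, replace=False)
            imgs, gts = _scene_batch(spec, batch, cfg.label_noise)
            x = Tensor(_to_input(imgs))
            raw = model(x)
            loss, _parts = detection_loss(model, raw, gts, state)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={loss.data!r}, "
                    f"parts={_parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
    else:
        losses = []

    map_trained, report = _eval_map(model, val_imgs, val_gts, cfg.n_classes,
                                    return_report=True)
    return TrainResult(map_trained, map_untrained, losses, report)


def _eval_map(model: DemoDetector, imgs: np.ndarray, gts, n_classes: int,
              return_report: bool = False):
    preds = model.predict(imgs)
    from .synthetic import CLASS_NAMES
    report = evaluate(gts, preds, CLASS_NAMES[:n_classes])
    if return_report:
        return report.map50, report
    return report.map50


# ---------------------------------------------------------------------------
# loss-robustness experiment
# ---------------------------------------------------------------------------

def box_regression_experiment(loss_name: str, seed: int, n_anchors: int = 48,
                              steps: int = 400, corrupt_frac: float = 0.1,
                              jitter: float = 0.8, lr: float = 0.02) -> float:
    """Median final IoU error on clean targets under corrupted supervision.

    A shared 4-16-4 tanh network refines each anchor box; supervision uses
    jittered labels for a seeded ``corrupt_frac`` of the anchors.  Returns
    ``median(1 - IoU(pred, clean_target))`` over the clean-label anchors
    after ``steps`` Adam iterations.
    """
    rng = np.random.default_rng(seed)
    canvas = 64.0
    tgt = np.column_stack([
        rng.uniform(16, 48, n_anchors), rng.uniform(16, 48, n_anchors),
        rng.uniform(8, 24, n_anchors), rng.uniform(8, 24, n_anchors)])
    # corrupted labels for a fraction of anchors
    bad = rng.random(n_anchors) < corrupt_frac
    labels = tgt.copy()
    labels[bad, 0] += rng.normal(0, jitter * labels[bad, 2])
    labels[bad, 1] += rng.normal(0, jitter * labels[bad, 3])
    labels[bad, 2] *= np.maximum(1 + rng.normal(0, jitter, bad.sum()), 0.25)
    labels[bad, 3] *= np.maximum(1 + rng.normal(0, jitter, bad.sum()), 0.25)
    labels[:, 2:] = np.maximum(labels[:, 2:], 1.0)
    # anchors: moderately perturbed versions of the targets
    anchors = tgt.copy()
    anchors[:, 0] += rng.normal(0, 5, n_anchors)
    anchors[:, 1] += rng.normal(0, 5, n_anchors)
    anchors[:, 2:] *= rng.uniform(0.6, 1.6, (n_anchors, 2))

    hid = 16
    w1 = Tensor(rng.normal(0, 0.3, (4, hid)), requires_grad=True)
    b1 = Tensor(np.zeros(hid), requires_grad=True)
    w2 = Tensor(np.zeros((hid, 4)), requires_grad=True)
    b2 = Tensor(np.zeros(4), requires_grad=True)
    params = [w1, b1, w2, b2]
    opt = Adam(params, lr=lr)
    feats = anchors / canvas
    a = Tensor(anchors)
    state = LossState()
    lab = Tensor(labels)
    for _ in range(steps):
        hidl = (Tensor(feats).matmul(w1) + b1).tanh()
        raw = hidl.matmul(w2) + b2
        pred = _decode_refine(a, raw)
        loss = box_loss(loss_name, pred, lab,
                        state if loss_name == "wiou3" else None)
        loss = loss.mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    hidl = (Tensor(feats).matmul(w1) + b1).tanh()
    pred = _decode_refine(a, hidl.matmul(w2) + b2).data
    errs = [1.0 - float(iou(pred[i], tgt[i])) for i in range(n_anchors) if not bad[i]]
    return float(np.median(errs))


def _decode_refine(anchors: Tensor, raw: Tensor) -> Tensor:
    cx = anchors[:, 0] + 12.0 * raw[:, 0].tanh()
    cy = anchors[:, 1] + 12.0 * raw[:, 1].tanh()
    w = anchors[:, 2] * raw[:, 2].tanh().exp()
    h = anchors[:, 3] * raw[:, 3].tanh().exp()
    return stack([cx, cy, w, h], axis=1)
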