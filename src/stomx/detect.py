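"""Anchor-based stomata detection and counting.

The detector follows the two-stage-detector training recipe: multi-scale,
multi-ratio anchors on a convolutional feature map, a softmax objectness
loss plus a smooth-L1 box-regression loss weighted by λ, cosine-annealed
learning rate, and score-thresholded counting of the final detections
(a box counts as a stoma only when its confidence exceeds 0.9).  The
backbone is a small residual network sized for CPU training; the anchor
configuration (scales 4/8/16, ratios 0.5/1/2), the λ = 10 loss balance and
the lr schedule follow the full-scale protocol and are all configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from . import _nn
from .types import Micrograph, StomaBox

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "smooth_l1",
    "detector_loss",
    "cosine_lr",
    "train_detector",
    "detect",
    "nms",
    "count_stomata",
    "finetune_detector",
    "save_detector",
    "load_detector",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Detector configuration (full-scale protocol defaults).

    ``small()`` is the desk-scale variant: 256x256 inputs (matching the
    synthetic scenes, so no resize), the same anchor grid, and a larger SGD
    step suited to training the shallow backbone from scratch.
    """

    input_size: Tuple[int, int] = (800, 600)  # (width, height)
    anchor_scales: Tuple[float, ...] = (4.0, 8.0, 16.0)
    anchor_ratios: Tuple[float, ...] = (0.5, 1.0, 2.0)
    anchor_base: float = 4.0  # pixels per unit anchor scale
    batch_size: int = 16
    lr_initial: float = 0.0005
    lr_final: float = 0.00005
    epochs: int = 20
    lambda_reg: float = 10.0
    backbone: str = "small-resnet"
    pretrained: bool = False
    momentum: float = 0.9
    stride: int = 8  # feature-map stride of the backbone
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    reg_iou: float = 0.3
    sample_size: int = 96
    pos_fraction: float = 0.33
    clip_norm: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_final >= self.lr_initial:
            raise ValueError("lr_final must be below lr_initial")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(s <= 0 for s in self.anchor_scales) or any(
            r <= 0 for r in self.anchor_ratios
        ):
            raise ValueError("anchor scales and ratios must be positive")

    @classmethod
    def small(cls, **overrides) -> "DetectorConfig":
        base = dict(input_size=(256, 256), lr_initial=0.02, lr_final=0.002, epochs=60)
        base.update(overrides)
        return cls(**base)

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_scales) * len(self.anchor_ratios)


def smooth_l1(x) -> np.ndarray:
    """Smooth-L1: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    x = np.asarray(x, float)
    ax = np.abs(x)
    out = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)
    return out if out.ndim else float(out)


def _smooth_l1_grad(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -1.0, 1.0)


def detector_loss(
    class_probs: np.ndarray,
    class_targets: np.ndarray,
    box_deltas: np.ndarray,
    box_targets: np.ndarray,
    cfg: DetectorConfig = DetectorConfig(),
    n_cls: Optional[int] = None,
    n_reg: Optional[int] = None,
) -> float:
    """Combined detection loss.

    ``(1/N_cls) Σ softmax-loss + λ (1/N_reg) Σ_pos smooth_l1(t - t*)`` summed
    coordinatewise over positive anchors (``class_targets == 1``).
    ``class_probs`` holds already-softmaxed per-class probabilities, one row
    per anchor.  With zero positive anchors the regression term is defined
    as 0.
    """
    probs = np.asarray(class_probs, float)
    targets = np.asarray(class_targets, int)
    n_cls = n_cls if n_cls is not None else len(targets)
    cls_term = float(
        np.sum(-np.log(np.clip(probs[np.arange(len(targets)), targets], 1e-12, None)))
        / n_cls
    )
    pos = targets == 1
    n_pos = int(pos.sum())
    n_reg = n_reg if n_reg is not None else max(n_pos, 1)
    if n_pos == 0:
        return cls_term
    resid = np.asarray(box_deltas, float)[pos] - np.asarray(box_targets, float)[pos]
    reg_term = cfg.lambda_reg * float(smooth_l1(resid).sum()) / n_reg
    return cls_term + reg_term


def cosine_lr(epoch: int, cfg: DetectorConfig) -> float:
    """lr(e) = lr_final + 0.5 (lr_initial - lr_final)(1 + cos(π e / epochs))."""
    if not (0 <= epoch <= cfg.epochs):
        raise ValueError(f"epoch must lie in [0, {cfg.epochs}]")
    return cfg.lr_final + 0.5 * (cfg.lr_initial - cfg.lr_final) * (
        1.0 + np.cos(np.pi * epoch / cfg.epochs)
    )


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def make_anchors(cfg: DetectorConfig, fh: int, fw: int) -> np.ndarray:
    """All anchors for an fh x fw feature map, as (n, 4) xyxy boxes.

    Anchor side for scale s is ``s * anchor_base`` pixels; ratio r scales the
    height by sqrt(r) and the width by 1/sqrt(r).
    """
    s = cfg.stride
    cx = (np.arange(fw) + 0.5) * s
    cy = (np.arange(fh) + 0.5) * s
    shapes = []
    for sc in cfg.anchor_scales:
        side = sc * cfg.anchor_base
        for r in cfg.anchor_ratios:
            shapes.append((side / np.sqrt(r), side * np.sqrt(r)))
    shapes = np.asarray(shapes)  # (A, 2) w,h
    gx, gy = np.meshgrid(cx, cy)  # (fh, fw)
    centers = np.stack([gx, gy], axis=-1).reshape(-1, 1, 2)  # (fh*fw,1,2)
    wh = shapes.reshape(1, -1, 2)
    mins = centers - wh / 2
    maxs = centers + wh / 2
    anchors = np.concatenate([mins, maxs], axis=-1).reshape(-1, 4)
    return anchors  # ordered location-major, anchor-shape-minor


def _iou_matrix(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    ix = np.maximum(
        0.0,
        np.minimum(anchors[:, None, 2], boxes[None, :, 2])
        - np.maximum(anchors[:, None, 0], boxes[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(anchors[:, None, 3], boxes[None, :, 3])
        - np.maximum(anchors[:, None, 1], boxes[None, :, 1]),
    )
    inter = ix * iy
    area_a = (anchors[:, 2] - anchors[:, 0]) * (anchors[:, 3] - anchors[:, 1])
    area_b = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _box_to_deltas(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = (anchors[:, 0] + anchors[:, 2]) / 2
    ay = (anchors[:, 1] + anchors[:, 3]) / 2
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bx = (boxes[:, 0] + boxes[:, 2]) / 2
    by = (boxes[:, 1] + boxes[:, 3]) / 2
    return np.stack(
        [(bx - ax) / aw, (by - ay) / ah, np.log(bw / aw), np.log(bh / ah)], axis=1
    )


def _deltas_to_boxes(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = (anchors[:, 0] + anchors[:, 2]) / 2
    ay = (anchors[:, 1] + anchors[:, 3]) / 2
    bx = deltas[:, 0] * aw + ax
    by = deltas[:, 1] * ah + ay
    bw = np.exp(np.clip(deltas[:, 2], -4, 4)) * aw
    bh = np.exp(np.clip(deltas[:, 3], -4, 4)) * ah
    return np.stack([bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2], axis=1)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _DetNet:
    """Shallow residual backbone (stride 8) + shared conv head.

    Head output per feature location: A anchors x (2 class logits + 4 box
    deltas).
    """

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator) -> None:
        A = cfg.n_anchors
        self.layers = [
            _nn.Conv2d(3, 12, 3, stride=2, rng=rng),
            _nn.ReLU(),
            _nn.ResidualBlock(12, rng),
            _nn.Conv2d(12, 24, 3, stride=2, rng=rng),
            _nn.ReLU(),
            _nn.ResidualBlock(24, rng),
            _nn.Conv2d(24, 48, 3, stride=2, rng=rng),
            _nn.ReLU(),
            _nn.ResidualBlock(48, rng),
            _nn.Conv2d(48, 64, 3, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(64, A * 6, 1, rng=rng),
        ]

    def params(self) -> list:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x  # (n, A*6, fh, fw)

    def backward(self, dout: np.ndarray) -> None:
        for l in reversed(self.layers):
            dout = l.backward(dout)


@dataclass
class DetectorModel:
    net: _DetNet
    cfg: DetectorConfig
    log: List[dict] = field(default_factory=list)


def _prep_image(image, cfg: DetectorConfig) -> Tuple[np.ndarray, float, float]:
    """Scale an image to the configured input size; returns (x, sx, sy)."""
    px = image.pixels if isinstance(image, Micrograph) else np.asarray(image)
    h0, w0 = px.shape[:2]
    w, h = cfg.input_size
    if (h0, w0) != (h, w):
        px = resize(px.astype(float), (h, w, 3), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        sx, sy = w / w0, h / h0
    else:
        px = px.astype(float)
        sx = sy = 1.0
    # per-image standardization keeps the backbone well conditioned
    mu = px.mean()
    sd = max(px.std(), 1.0)
    x = ((px - mu) / sd).transpose(2, 0, 1).astype(np.float32)
    return x, sx, sy


def _head_views(out: np.ndarray, A: int):
    """Reshape the head output to anchor-ordered logits and deltas."""
    n, ch, fh, fw = out.shape
    v = out.reshape(n, A, 6, fh, fw)
    # match make_anchors ordering: location-major, shape-minor
    logits = v[:, :, :2].transpose(0, 3, 4, 1, 2).reshape(n, fh * fw * A, 2)
    deltas = v[:, :, 2:].transpose(0, 3, 4, 1, 2).reshape(n, fh * fw * A, 4)
    return logits, deltas


def _assign_anchors(anchors: np.ndarray, truths: np.ndarray, cfg: DetectorConfig):
    """Anchor labels (1 pos / 0 neg / -1 ignore), matched truth and reg mask.

    The regression mask extends below the positive threshold (down to
    ``reg_iou``): anchors with moderate overlap also learn to point at their
    truth box, so duplicate firings collapse onto one rectangle and die in
    NMS.
    """
    n = anchors.shape[0]
    labels = np.full(n, -1, np.int8)
    matched = np.zeros(n, np.int32)
    if len(truths) == 0:
        labels[:] = 0
        return labels, matched, np.zeros(n, bool), np.zeros(n, bool)
    ious = _iou_matrix(anchors, truths)
    best_truth = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_truth]
    labels[best_iou < cfg.neg_iou] = 0
    labels[best_iou >= cfg.pos_iou] = 1
    reg_mask = best_iou >= cfg.reg_iou
    near = (best_iou > 0.02) & (best_iou < cfg.neg_iou)
    # every truth claims its best anchor so no object goes unsupervised
    for j in range(len(truths)):
        i = int(ious[:, j].argmax())
        labels[i] = 1
        reg_mask[i] = True
        best_truth[i] = j
    matched = best_truth
    return labels, matched, reg_mask, near


def train_detector(
    train_set: Sequence[tuple],
    cfg: DetectorConfig,
    model: Optional[DetectorModel] = None,
    lr_override: Optional[Tuple[float, float]] = None,
) -> DetectorModel:
    """Train the detector on (image, [StomaBox, ...]) pairs.

    Optimizes the combined softmax + λ-weighted smooth-L1 objective over
    sampled anchors with momentum SGD under cosine annealing.  Seeded and
    deterministic.  Pass ``model`` to continue from a checkpoint (used by
    :func:`finetune_detector`).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, sample_rng, shuffle_rng = [np.random.default_rng(c) for c in ss.spawn(3)]
    if model is None:
        model = DetectorModel(_DetNet(cfg, init_rng), cfg)
    net = model.net
    lr0, lr1 = (cfg.lr_initial, cfg.lr_final) if lr_override is None else lr_override
    opt = _nn.SGD(net.params(), lr0, cfg.momentum, clip_norm=cfg.clip_norm)
    A = cfg.n_anchors
    w, h = cfg.input_size
    fh, fw = h // cfg.stride, w // cfg.stride
    anchors = make_anchors(cfg, fh, fw)

    # pre-scale images and targets once
    prepared = []
    for image, boxes in train_set:
        x, sx, sy = _prep_image(image, cfg)
        tb = np.asarray(
            [[b.xmin * sx, b.ymin * sy, b.xmax * sx, b.ymax * sy] for b in boxes],
            float,
        ).reshape(-1, 4)
        labels, matched, reg_mask, near = _assign_anchors(anchors, tb, cfg)
        targets = (
            _box_to_deltas(tb[matched], anchors) if len(tb) else np.zeros((len(anchors), 4))
        )
        prepared.append((x, labels, targets, reg_mask, near))

    for epoch in range(cfg.epochs):
        if lr_override is None:
            opt.lr = cosine_lr(epoch, cfg)
        else:
            opt.lr = (
                lr1 + 0.5 * (lr0 - lr1) * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
                if lr0 > 0
                else 0.0
            )
        order = shuffle_rng.permutation(len(prepared))
        losses = []
        for idx in order:
            x, labels, targets, reg_mask, near = prepared[idx]
            out = net.forward(x[None], train=True)
            logits, deltas = _head_views(out, A)
            logits, deltas = logits[0], deltas[0]

            pos_ids = np.nonzero(labels == 1)[0]
            n_pos_keep = min(len(pos_ids), int(cfg.sample_size * cfg.pos_fraction))
            if len(pos_ids) > n_pos_keep:
                pos_ids = sample_rng.choice(pos_ids, n_pos_keep, replace=False)
            n_neg = cfg.sample_size - len(pos_ids)
            # half the negatives come from anchors that graze an object:
            # these hard negatives are what stops duplicate firings
            near_ids = np.nonzero(near)[0]
            n_near = min(len(near_ids), n_neg // 2)
            near_pick = (
                sample_rng.choice(near_ids, n_near, replace=False)
                if n_near
                else np.empty(0, int)
            )
            far_ids = np.nonzero((labels == 0) & ~near)[0]
            n_far = min(len(far_ids), n_neg - n_near)
            far_pick = sample_rng.choice(far_ids, n_far, replace=False)
            sampled = np.concatenate([pos_ids, near_pick, far_pick]).astype(int)
            targ = (labels[sampled] == 1).astype(int)

            cls_losses, dlogit_rows = _nn.softmax_cross_entropy(logits[sampled], targ)
            n_cls = len(sampled)
            # λ/N_reg is chosen so one regression anchor weighs the same as
            # one classification sample, the balance the λ=10 recipe aims at
            n_reg = int(cfg.lambda_reg * n_cls)
            loss = float(cls_losses.sum() / n_cls)
            dlogits = np.zeros_like(logits)
            dlogits[sampled] = dlogit_rows / n_cls
            ddeltas = np.zeros_like(deltas)
            reg_ids = np.nonzero(reg_mask)[0]
            if len(reg_ids):
                resid = deltas[reg_ids] - targets[reg_ids]
                loss += cfg.lambda_reg * float(smooth_l1(resid).sum()) / n_reg
                ddeltas[reg_ids] = cfg.lambda_reg * _smooth_l1_grad(resid) / n_reg
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")

            dout = np.zeros((1, fh * fw * A, 6), np.float32)
            dout[0, :, :2] = dlogits
            dout[0, :, 2:] = ddeltas
            dout = (
                dout.reshape(1, fh, fw, A, 6).transpose(0, 3, 4, 1, 2).reshape(1, A * 6, fh, fw)
            )
            opt.zero_grad()
            net.backward(dout)
            opt.step()
            losses.append(loss)
        model.log.append({"epoch": epoch, "lr": float(opt.lr), "loss": float(np.mean(losses))})
    return model


def nms(boxes: Sequence[StomaBox], iou_thr: float = 0.5) -> List[StomaBox]:
    """Non-maximum suppression; score ties broken by box coordinates."""
    from .metrics import iou as _iou

    order = sorted(boxes, key=lambda b: (-(b.score or 0.0), b.xmin, b.ymin, b.xmax, b.ymax))
    keep: List[StomaBox] = []
    for b in order:
        if all(_iou(b, k) <= iou_thr for k in keep):
            keep.append(b)
    return keep


def detect(
    model: DetectorModel,
    micrograph,
    nms_iou: float = 0.5,
    score_min: float = 0.05,
    max_detections: int = 300,
) -> List[StomaBox]:
    """Run the detector on one micrograph; returns scored, NMS-filtered boxes
    in the original image's coordinates."""
    cfg = model.cfg
    x, sx, sy = _prep_image(micrograph, cfg)
    w, h = cfg.input_size
    fh, fw = h // cfg.stride, w // cfg.stride
    anchors = make_anchors(cfg, fh, fw)
    out = model.net.forward(x[None], train=False)
    logits, deltas = _head_views(out, cfg.n_anchors)
    z = logits[0] - logits[0].max(axis=1, keepdims=True)
    ez = np.exp(z)
    scores = (ez[:, 1] / ez.sum(axis=1))
    keep = scores >= score_min
    if not keep.any():
        return []
    boxes = _deltas_to_boxes(deltas[0][keep], anchors[keep])
    ss = scores[keep]
    cands = []
    px = micrograph.pixels if isinstance(micrograph, Micrograph) else np.asarray(micrograph)
    h0, w0 = px.shape[:2]
    for (x1, y1, x2, y2), s in zip(boxes, ss):
        x1, y1 = max(0.0, x1 / sx), max(0.0, y1 / sy)
        x2, y2 = min(float(w0), x2 / sx), min(float(h0), y2 / sy)
        if x2 - x1 >= 1.0 and y2 - y1 >= 1.0:
            cands.append(StomaBox(x1, y1, x2, y2, float(np.clip(s, 0.0, 1.0))))
    cands.sort(key=lambda b: (-(b.score or 0.0), b.xmin, b.ymin, b.xmax, b.ymax))
    return nms(cands[: max(4 * max_detections, 400)], nms_iou)[:max_detections]


def count_stomata(detections: Sequence[StomaBox], threshold: float = 0.9) -> int:
    """Number of detections with confidence strictly above the threshold."""
    return sum(1 for b in detections if (b.score or 0.0) > threshold)


def finetune_detector(
    model: DetectorModel,
    new_train_set: Sequence[tuple],
    lr: float = 0.0001,
    epochs: int = 20,
    seed: int = 0,
) -> DetectorModel:
    """Continue training all layers from a checkpoint with a smaller rate
    (cosine-annealed from ``lr`` to ``lr / 10``; ``lr=0`` is a no-op)."""
    import copy
    from dataclasses import replace as _replace

    cfg = _replace(model.cfg, epochs=epochs, seed=seed)
    clone = copy.deepcopy(model)  # the checkpoint argument stays untouched
    if lr > 0:
        return train_detector(new_train_set, cfg, model=clone, lr_override=(lr, lr / 10.0))
    # lr = 0: no updates at all
    return clone


def export_detections_csv(per_image: dict, path) -> None:
    """Write detections as CSV rows (image_id, xmin, ymin, xmax, ymax, score).

    ``per_image`` maps image id -> list of scored StomaBox.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "xmin", "ymin", "xmax", "ymax", "score"])
        for image_id, boxes in per_image.items():
            for b in boxes:
                writer.writerow([image_id, b.xmin, b.ymin, b.xmax, b.ymax, b.score])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_detector(model: DetectorModel, path) -> None:
    arrays = {}
    for i, (p, _) in enumerate(model.net.params()):
        arrays[f"p_{i}"] = p
    meta = {"cfg": asdict(model.cfg), "log": model.log}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8), **arrays)


def load_detector(path) -> DetectorModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tolist()).decode())
        cfg_d = meta["cfg"]
        for key in ("input_size", "anchor_scales", "anchor_ratios"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = DetectorConfig(**cfg_d)
        net = _DetNet(cfg, np.random.default_rng(cfg.seed))
        params = net.params()
        for i, (p, _) in enumerate(params):
            key = f"p_{i}"
            if key not in data:
                raise ValueError(f"incompatible checkpoint: missing {key}")
            if p.shape != data[key].shape:
                raise ValueError(
                    f"incompatible checkpoint: {key} has shape {data[key].shape}, "
                    f"expected {p.shape}"
                )
            p[...] = data[key]
    return DetectorModel(net, cfg, meta["log"])
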