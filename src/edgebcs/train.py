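"""Training loop, augmentation pipeline and inference helpers.

Training follows the donor family's recipe: SGD with momentum 0.937 and
weight decay 5e-4 at initial learning rate 0.01 (linear decay), batch 16,
100 epochs at 640x640, with HSV colour jitter (0.015/0.7/0.4), translation
0.1, scaling 0.5, horizontal flip 0.5 and mosaic composition active through
every epoch.  Focal+global feature distillation from a frozen teacher can be
enabled; it touches only the training graph.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor

from .autograd import Tensor, no_grad
from .assembly import Detector, ModelConfig, build_model, save_checkpoint
from .data import read_yolo_labels, load_image
from .distill import DistillConfig, FGDLoss, build_focal_masks
from .head import make_anchors, flatten_predictions, decode_boxes
from .loss import DetectionLoss
from .metrics import Detection, GroundTruth, nms, evaluate_detections


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    imgsz: int = 640
    lr0: float = 0.01
    lrf: float = 0.01            # final lr fraction (linear decay)
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: int = 3
    optimizer: str = "sgd"          # "sgd" (study recipe) or "adamw"
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    translate: float = 0.1
    scale: float = 0.5
    fliplr: float = 0.5
    mosaic: float = 1.0
    nms_iou: float = 0.7
    conf_thres: float = 0.25
    seed: int = 0
    distill: bool = False
    distill_cfg: DistillConfig = field(default_factory=DistillConfig)

    def __post_init__(self):
        for p in ("fliplr", "mosaic"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be a probability")
        if self.lr0 <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def from_yaml(cls, path):
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dc = raw.pop("distill_cfg", None)
        cfg = cls(**raw)
        if dc:
            cfg.distill_cfg = DistillConfig(**dc)
        return cfg


class DetDataset:
    """Images + YOLO labels for one split of a generated/collected set."""

    def __init__(self, root, split="train", imgsz=640):
        self.root = Path(root)
        self.imgsz = imgsz
        manifest = pd.read_csv(self.root / "manifest.csv")
        self.rows = manifest[manifest["split"] == split].reset_index(drop=True)
        if len(self.rows) == 0:
            raise ValueError(f"empty split {split!r}")
        self.split = split

    def __len__(self):
        return len(self.rows)

    def load(self, i):
        """Returns image float32 (3, s, s) in [0,1] and (classes, boxes px)."""
        row = self.rows.iloc[i]
        img = load_image(self.root / "images" / self.split / row["image"])
        img = np.asarray(
            Image.fromarray(img).resize((self.imgsz, self.imgsz),
                                        Image.BILINEAR))
        labels = read_yolo_labels(
            self.root / "labels" / self.split / (row["image"][:-4] + ".txt"))
        cls = np.array([l[0] for l in labels], int)
        s = self.imgsz
        boxes = np.array([[(l[1] - l[3] / 2) * s, (l[2] - l[4] / 2) * s,
                           (l[1] + l[3] / 2) * s, (l[2] + l[4] / 2) * s]
                          for l in labels], np.float32).reshape(-1, 4)
        return img.astype(np.float32) / 255.0, cls, boxes


# -- augmentations -------------------------------------------------------------
def hsv_jitter(img, rng, h=0.015, s=0.7, v=0.4):
    """Random hue/saturation/value gains on an RGB [0,1] image."""
    if h == s == v == 0:
        return img
    gains = 1.0 + rng.uniform(-1, 1, 3) * np.array([h, s, v])
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] * gains[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * gains[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * gains[2], 0, 1)
    return skcolor.hsv2rgb(hsv).astype(np.float32)


def affine_jitter(img, boxes, rng, translate=0.1, scale=0.5):
    """Random scale + translation; boxes clipped, degenerate ones dropped."""
    s = img.shape[0]
    zoom = 1.0 + rng.uniform(-scale, scale)
    tx = rng.uniform(-translate, translate) * s
    ty = rng.uniform(-translate, translate) * s
    pil = Image.fromarray((img * 255).astype(np.uint8))
    # inverse map: output(x, y) = input(a x + b y + c, d x + e y + f)
    inv = (1 / zoom, 0, -tx / zoom, 0, 1 / zoom, -ty / zoom)
    out = pil.transform((s, s), Image.AFFINE, inv, Image.BILINEAR)
    out = np.asarray(out, np.float32) / 255.0
    new = boxes * zoom + np.array([tx, ty, tx, ty], np.float32)
    new = new.clip(0, s - 1)
    keep = (new[:, 2] - new[:, 0] > 2) & (new[:, 3] - new[:, 1] > 2)
    return out, new[keep], keep


def horizontal_flip(img, boxes):
    s = img.shape[1]
    out = img[:, ::-1].copy()
    new = boxes.copy()
    new[:, 0], new[:, 2] = s - boxes[:, 2], s - boxes[:, 0]
    return out, new


def mosaic4(samples, rng):
    """Compose four (img, cls, boxes) samples on a 2x2 canvas, then halve."""
    s = samples[0][0].shape[0]
    canvas = np.zeros((2 * s, 2 * s, 3), np.float32)
    all_cls, all_boxes = [], []
    for q, (img, cls, boxes) in enumerate(samples):
        oy, ox = (q // 2) * s, (q % 2) * s
        canvas[oy:oy + s, ox:ox + s] = img
        if len(boxes):
            all_boxes.append(boxes + [ox, oy, ox, oy])
            all_cls.append(cls)
    big = np.asarray(Image.fromarray((canvas * 255).astype(np.uint8))
                     .resize((s, s), Image.BILINEAR), np.float32) / 255.0
    if all_boxes:
        boxes = np.concatenate(all_boxes) / 2.0
        cls = np.concatenate(all_cls)
    else:
        boxes = np.zeros((0, 4), np.float32)
        cls = np.zeros(0, int)
    return big, cls, boxes


def build_batch(dataset, indices, cfg: TrainConfig, rng, augment=True):
    imgs, targets = [], []
    for i in indices:
        if augment and rng.random() < cfg.mosaic:
            picks = [i] + list(rng.integers(0, len(dataset), 3))
            img, cls, boxes = mosaic4([dataset.load(j) for j in picks], rng)
        else:
            img, cls, boxes = dataset.load(i)
        if augment:
            img = hsv_jitter(img, rng, cfg.hsv_h, cfg.hsv_s, cfg.hsv_v)
            img, boxes, keep = affine_jitter(img, boxes, rng,
                                             cfg.translate, cfg.scale)
            cls = cls[keep]
            if rng.random() < cfg.fliplr:
                img, boxes = horizontal_flip(img, boxes)
        imgs.append(img.transpose(2, 0, 1))
        targets.append((cls, boxes))
    return Tensor(np.stack(imgs)), targets


# -- optimizer -----------------------------------------------------------------
class SGD:
    def __init__(self, params, lr, momentum=0.937, weight_decay=0.0005,
                 clip_norm=10.0):
        self.params = list(params)
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.clip_norm = clip_norm
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        if self.clip_norm:
            total = math.sqrt(sum(float((p.grad ** 2).sum())
                                  for p in self.params if p.grad is not None))
            scale = self.clip_norm / (total + 1e-12) if total > self.clip_norm \
                else 1.0
        else:
            scale = 1.0
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale + self.wd * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class AdamW:
    """AdamW with decoupled weight decay and gradient-norm clipping."""

    def __init__(self, params, lr=0.001667, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0005, clip_norm=10.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        if self.clip_norm:
            total = math.sqrt(sum(float((p.grad ** 2).sum())
                                  for p in self.params if p.grad is not None))
            scale = self.clip_norm / (total + 1e-12) if total > self.clip_norm \
                else 1.0
        else:
            scale = 1.0
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def make_optimizer(params, cfg: "TrainConfig"):
    if cfg.optimizer == "adamw":
        return AdamW(params, lr=cfg.lr0, weight_decay=cfg.weight_decay)
    return SGD(params, cfg.lr0, cfg.momentum, cfg.weight_decay)


# -- inference -----------------------------------------------------------------
def predict(model: Detector, images: Tensor, conf_thres=0.25, iou_thres=0.7,
            image_ids=None) -> list[Detection]:
    """Forward + decode + confidence filter + class-aware NMS."""
    model.eval()
    with no_grad():
        raw = model(images)
        cls_logits, reg, shapes = flatten_predictions(raw, model.cfg.reg_max)
        anchors, strides = make_anchors(shapes, model.strides)
        boxes = decode_boxes(reg, anchors, strides, model.cfg.reg_max).data
        scores = 1.0 / (1.0 + np.exp(-cls_logits.data))
    dets = []
    N = scores.shape[0]
    ids = image_ids if image_ids is not None else list(range(N))
    for n in range(N):
        cand = []
        conf = scores[n].max(axis=1)
        cls = scores[n].argmax(axis=1)
        for a in np.where(conf >= conf_thres)[0]:
            x1, y1, x2, y2 = boxes[n, a]
            if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                continue
            cand.append(Detection((float(x1), float(y1), float(x2), float(y2)),
                                  int(cls[a]), float(conf[a]), ids[n]))
        dets.extend(nms(cand, iou_thres))
    return dets


def evaluate(model: Detector, dataset: DetDataset, cfg: TrainConfig,
             conf_thres=0.001, max_batch=8) -> dict:
    dets, truths = [], []
    for start in range(0, len(dataset), max_batch):
        idx = range(start, min(start + max_batch, len(dataset)))
        imgs, targets = build_batch(dataset, idx, cfg, np.random.default_rng(0),
                                    augment=False)
        dets.extend(predict(model, imgs, conf_thres, cfg.nms_iou,
                            image_ids=list(idx)))
        for i, (cls, boxes) in zip(idx, targets):
            truths.extend(GroundTruth(tuple(b), int(c), i)
                          for c, b in zip(cls, boxes))
    return evaluate_detections(dets, truths,
                               classes=list(range(model.cfg.nc)))


# -- training loop -------------------------------------------------------------
def train(model: Detector, data_root, cfg: TrainConfig,
          teacher: Detector | None = None, out_dir=None,
          eval_every: int = 10, log_fn=None) -> dict:
    """Train ``model``; returns history and writes the best-mAP checkpoint.

    With ``cfg.distill`` a frozen ``teacher`` provides neck features for the
    focal+global distillation term; distillation parameters (adapters,
    context block) live outside the detector and are dropped after training.
    """
    rng = np.random.default_rng(cfg.seed)
    train_set = DetDataset(data_root, "train", cfg.imgsz)
    try:
        val_set = DetDataset(data_root, "val", cfg.imgsz)
    except ValueError:
        val_set = train_set
    loss_fn = DetectionLoss(nc=model.cfg.nc, reg_max=model.cfg.reg_max,
                            strides=model.strides)
    params = model.parameters()
    distillers = []
    if cfg.distill:
        if teacher is None:
            raise ValueError("distillation requires a teacher model")
        # teacher features use batch statistics (momentum 0: buffers stay
        # frozen) so teacher and student normalisation behave identically
        teacher.train()
        from . import nn as _nn
        for m in teacher.modules():
            if isinstance(m, _nn.BatchNorm2d):
                m.momentum = 0.0
        s_ch = model.neck.out_channels
        t_ch = teacher.neck.out_channels
        distillers = [FGDLoss(s, t, cfg.distill_cfg)
                      for s, t in zip(s_ch, t_ch)]
        for d in distillers:
            params = params + d.parameters()
    opt = make_optimizer(params, cfg)
    steps_per_epoch = max(1, len(train_set) // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    history, best_map, step = [], -1.0, 0
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, parts_acc = 0.0, {}
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            imgs, targets = build_batch(train_set, idx, cfg, rng)
            warmup_steps = cfg.warmup_epochs * steps_per_epoch
            if step < warmup_steps:
                opt.lr = cfg.lr0 * (step + 1) / warmup_steps
            else:
                opt.lr = cfg.lr0 * (1.0 - step / total_steps * (1.0 - cfg.lrf))
            s_feats = model.forward_features(imgs)
            raw = model.head(s_feats)
            total, parts = loss_fn(raw, targets)
            if distillers:
                d_loss, d_parts = _distill_term(teacher, distillers, imgs,
                                                targets, s_feats,
                                                model.strides)
                total = total + d_loss
                parts.update(d_parts)
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += total.item()
            for k, v in parts.items():
                parts_acc[k] = parts_acc.get(k, 0.0) + v / steps_per_epoch
            step += 1
        rec = {"epoch": epoch, "loss": epoch_loss / steps_per_epoch,
               **{f"loss_{k}": v for k, v in parts_acc.items()}}
        if (epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1:
            metrics = evaluate(model, val_set, cfg)
            rec.update({"map50": metrics["map50"],
                        "map50_95": metrics["map50_95"],
                        "precision": metrics["precision"],
                        "recall": metrics["recall"]})
            if metrics["map50"] > best_map and out_dir:
                best_map = metrics["map50"]
                save_checkpoint(model, out_dir / "best.npz")
        history.append(rec)
        if log_fn:
            log_fn(rec)
        if out_dir:
            with open(out_dir / "history.jsonl", "a") as fh:
                fh.write(json.dumps(rec) + "\n")
    if out_dir:
        save_checkpoint(model, out_dir / "last.npz")
    return {"history": history, "best_map50": best_map}


def _distill_term(teacher, distillers, imgs, targets, s_feats, strides):
    """FGD loss over the three neck levels, masks rebuilt per level."""
    with no_grad():
        t_feats = teacher.forward_features(imgs)
    total = Tensor(0.0)
    parts = {}
    N = imgs.shape[0]
    for lvl, (fs, ft, dist, stride) in enumerate(
            zip(s_feats, t_feats, distillers, strides)):
        for n in range(N):
            boxes = targets[n][1]
            masks = build_focal_masks(boxes, ft.shape[1:], ft.data[n],
                                      stride, dist.cfg)
            l, p = dist(ft[n], fs[n], masks)
            total = total + l
            for k, v in p.items():
                parts[f"distill_{k}"] = parts.get(f"distill_{k}", 0.0) + v
    return total, parts
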