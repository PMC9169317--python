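"""Training recipe: losses, poly learning-rate decay, preprocessing,
augmentation, patch sampling, and the Adam training loop.

The loss is the sum of a soft Dice loss

    Dice = 2 Σ p q / (Σ p² + Σ q²),     L_dice = 1 − Dice

and a class-weighted binary cross-entropy, with the positive-class weight
defaulting to the batch background/foreground pixel ratio.  The learning
rate follows a polynomial decay: lr(epoch) = lr0 · (1 − (epoch−1)/total)^power
with power 0.9, evaluated per epoch over 200 epochs at lr0 = 1e−3; Adam uses
β1 = 0.5, β2 = 0.999.
"""

from __future__ import annotations

import csv
import io
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from skimage import color as _skcolor
from skimage import exposure as _skexposure
from skimage import transform as _sktransform

from .network import DNLNet, predict_image
from .nn import Adam, Tensor, as_tensor

__all__ = ["TrainConfig", "poly_lr_factor", "dice_loss",
           "weighted_cross_entropy", "combined_loss", "preprocess_drive_style",
           "sample_patches", "augment_ibv_style", "train", "TrainLog"]

EPS = 1e-7   # loss clamping / Dice denominator stabiliser


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and data-handling settings.

    Defaults encode the published recipe: Adam(β1=0.5, β2=0.999),
    lr0 = 1e-3 with poly(0.9) decay over 200 epochs, batch 4, 96x96 patches.
    """
    beta1: float = 0.5
    beta2: float = 0.999
    initial_lr: float = 1e-3
    power: float = 0.9
    total_epochs: int = 200
    batch_size: int = 4
    patch_size: int = 96
    dice_w: float = 1.0
    wce_w: float = 1.0
    w_pos: float | None = None      # None: background/foreground ratio per batch
    augment: bool = False           # affine/rotation/vflip on each sample
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls(**yaml.safe_load(text))


# --------------------------------------------------------------------------
# Schedule
# --------------------------------------------------------------------------

def poly_lr_factor(epoch: int, total: int, power: float) -> float:
    """Multiplicative lr factor (1 − (epoch−1)/total)^power, epoch in 1..total."""
    if not 1 <= epoch <= total:
        raise ValueError(f"epoch {epoch} outside 1..{total}")
    return float((1.0 - (epoch - 1) / total) ** power)


# --------------------------------------------------------------------------
# Losses (accept numpy arrays or autodiff Tensors)
# --------------------------------------------------------------------------

def _pair(pred, target) -> tuple[Tensor, Tensor]:
    p, t = as_tensor(pred), as_tensor(target)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target {t.shape}")
    return p, t


def _scalar(x):
    return float(x.data) if isinstance(x, Tensor) else float(x)


def dice_loss(pred, target):
    """1 − soft Dice with squared-sum denominator; 0 at a perfect match.

    An all-zero prediction/target pair returns 0 through the epsilon-
    stabilised quotient (2·0+eps)/(0+eps) = 1.
    """
    p, t = _pair(pred, target)
    num = 2.0 * (p * t).sum() + EPS
    den = (p * p).sum() + (t * t).sum() + EPS
    out = 1.0 - num / den
    return out if _needs_graph(pred, target) else _scalar(out)


def weighted_cross_entropy(pred, target, w_pos: float = 1.0):
    """Mean over pixels of −[w_pos·t·log p + (1−t)·log(1−p)], p clamped."""
    p, t = _pair(pred, target)
    p = p.clip(EPS, 1.0 - EPS)
    ll = w_pos * t * p.log() + (1.0 - t) * (1.0 - p).log()
    out = -ll.mean()
    return out if _needs_graph(pred, target) else _scalar(out)


def combined_loss(pred, target, cfg: TrainConfig | None = None):
    """dice_w · Dice loss + wce_w · weighted cross-entropy."""
    cfg = cfg if cfg is not None else TrainConfig()
    w_pos = cfg.w_pos
    if w_pos is None:
        t = target.data if isinstance(target, Tensor) else np.asarray(target)
        pos = float(t.sum())
        neg = float(t.size - pos)
        w_pos = neg / pos if pos > 0 else 1.0
    out = (cfg.dice_w * dice_loss(pred, target)
           + cfg.wce_w * weighted_cross_entropy(pred, target, w_pos))
    return out


def _needs_graph(*args) -> bool:
    return any(isinstance(a, Tensor) and (a.requires_grad or a._prev)
               for a in args)


# --------------------------------------------------------------------------
# Preprocessing and augmentation
# --------------------------------------------------------------------------

def preprocess_drive_style(image: np.ndarray, clahe: bool = True,
                           clip_limit: float = 0.01, tile_size: int = 8,
                           gamma: float = 1.2, standardize: bool = True
                           ) -> np.ndarray:
    """Fundus-style pipeline: grayscale -> standardise -> CLAHE -> gamma.

    Standardisation is per-image zero-mean/unit-variance (epsilon-stabilised
    for constant images).  CLAHE operates on a min-max rescaled copy, so the
    output of the CLAHE and gamma steps lives in [0, 1]; with both disabled
    the standardised image is returned unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        if img.shape[0] in (3, 4):          # channel-first to channel-last
            img = np.moveaxis(img, 0, -1)
        img = _skcolor.rgb2gray(img[..., :3])
    if standardize:
        img = (img - img.mean()) / (img.std() + EPS)
    if clahe:
        lo, hi = img.min(), img.max()
        unit = (img - lo) / (hi - lo + EPS)
        kernel = max(img.shape[0] // tile_size, 1), max(img.shape[1] // tile_size, 1)
        img = _skexposure.equalize_adapthist(unit, kernel_size=kernel,
                                             clip_limit=clip_limit)
    if gamma != 1.0:
        lo, hi = img.min(), img.max()
        unit = (img - lo) / (hi - lo + EPS)
        img = unit ** gamma
    return img


def sample_patches(image: np.ndarray, mask: np.ndarray, n: int, size: int,
                   seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Congruent random patches with centres uniform over the full image.

    Centres near the border are handled by reflect padding, so thin border
    vessels remain sampleable.  Fully deterministic for a given seed.
    """
    if n <= 0:
        return []
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError("image and mask shapes are incongruent")
    rng = np.random.default_rng(seed)
    h, w = image.shape[-2:]
    pad = size  # generous; any centre yields a full window
    pimg = np.pad(image, _pad_spec(image.ndim, pad), mode="reflect")
    pmsk = np.pad(mask, _pad_spec(mask.ndim, pad), mode="reflect")
    out = []
    for _ in range(n):
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        top = cy - size // 2 + pad
        left = cx - size // 2 + pad
        out.append((pimg[..., top:top + size, left:left + size].copy(),
                    pmsk[..., top:top + size, left:left + size].copy()))
    return out


def _pad_spec(ndim: int, pad: int):
    return [(0, 0)] * (ndim - 2) + [(pad, pad), (pad, pad)]


def augment_ibv_style(image: np.ndarray, mask: np.ndarray, seed: int,
                      max_rotation: float = 15.0, max_scale: float = 0.1,
                      max_shear: float = 0.05, flip_prob: float = 0.5
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Random affine + rotation + vertical flip, applied identically to the
    image and its mask; the mask is resampled nearest-neighbour so it stays
    binary."""
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    h, w = image.shape[-2:]
    angle = np.deg2rad(rng.uniform(-max_rotation, max_rotation))
    scale = 1.0 + rng.uniform(-max_scale, max_scale)
    shear = rng.uniform(-max_shear, max_shear)
    do_flip = rng.random() < flip_prob
    centre = np.array([w, h]) / 2.0 - 0.5
    tf = (_sktransform.AffineTransform(translation=-centre)
          + _sktransform.AffineTransform(rotation=angle, scale=scale,
                                         shear=shear)
          + _sktransform.AffineTransform(translation=centre))

    def warp(arr: np.ndarray, order: int) -> np.ndarray:
        if arr.ndim == 3:
            return np.stack([warp(ch, order) for ch in arr])
        out = _sktransform.warp(arr, tf.inverse, order=order, mode="reflect",
                                preserve_range=True)
        return np.flipud(out).copy() if do_flip else out

    aug_img = warp(image, order=1)
    aug_msk = warp(mask, order=0)
    return aug_img, (aug_msk > 0.5).astype(mask.dtype)


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

@dataclass
class TrainLog:
    """Per-epoch record: (epoch, lr, train_loss, val_dice)."""
    rows: list[tuple[int, float, float, float]] = field(default_factory=list)
    best_epoch: int = 0
    best_val_dice: float = -np.inf

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["epoch", "lr", "train_loss", "val_dice"])
        writer.writerows(self.rows)
        return buf.getvalue()


def _soft_dice(pred: np.ndarray, target: np.ndarray) -> float:
    num = 2.0 * float((pred * target).sum()) + EPS
    den = float((pred * pred).sum() + (target * target).sum()) + EPS
    return num / den


def train(model: DNLNet, dataset, cfg: TrainConfig | None = None,
          epochs: int | None = None, log_path=None) -> TrainLog:
    """Train in place with Adam + poly decay; restores the best-validation
    weights before returning the log.

    `dataset` yields (image, mask) pairs as (C,)H x W arrays.  A seeded
    `val_fraction` split is held out; the checkpointed state is the epoch
    with the highest held-out soft Dice.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    pairs = [(np.asarray(img, dtype=np.float64), np.asarray(msk, dtype=np.float64))
             for img, msk in dataset]
    if not pairs:
        raise ValueError("empty dataset")
    pairs = [(img[None] if img.ndim == 2 else img,
              msk[None] if msk.ndim == 2 else msk) for img, msk in pairs]

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    n_val = max(int(round(cfg.val_fraction * len(pairs))), 1) \
        if len(pairs) > 1 else 0
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order

    opt = Adam(model.parameters(), lr=cfg.initial_lr,
               betas=(cfg.beta1, cfg.beta2))
    total = epochs if epochs is not None else cfg.total_epochs
    log = TrainLog()
    best_state = model.state_dict()

    for epoch in range(1, total + 1):
        lr = cfg.initial_lr * poly_lr_factor(epoch, total, cfg.power)
        opt.lr = lr
        model.train()
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            imgs, msks = [], []
            for k, idx in enumerate(batch):
                img, msk = pairs[idx]
                if cfg.augment:
                    aug_seed = int(rng.integers(0, 2 ** 31))
                    img, msk = augment_ibv_style(img, msk, aug_seed)
                h, w = img.shape[-2:]
                if cfg.patch_size and (h > cfg.patch_size
                                       or w > cfg.patch_size):
                    patch_seed = int(rng.integers(0, 2 ** 31))
                    img, msk = sample_patches(img, msk, 1, cfg.patch_size,
                                              patch_seed)[0]
                imgs.append(img)
                msks.append(msk)
            x = Tensor(np.stack(imgs))
            t = Tensor(np.stack(msks))
            pred = model(x)
            loss = combined_loss(pred, t, cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        model.eval()
        val_dices = []
        for idx in val_idx:
            img, msk = pairs[idx]
            prob = predict_image(model, img)   # pads to the stage multiple
            val_dices.append(_soft_dice(prob, msk[0]))
        val_dice = float(np.mean(val_dices)) if val_dices else float("nan")
        log.rows.append((epoch, lr, float(np.mean(losses)), val_dice))
        if val_dices and val_dice > log.best_val_dice:
            log.best_val_dice = val_dice
            log.best_epoch = epoch
            best_state = model.state_dict()

    if log.best_epoch:
        model.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write(log.to_csv())
    return log
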