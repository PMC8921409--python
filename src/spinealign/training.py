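"""Training of the cascade detection models.

Each model regresses landmark coordinates normalized to [0, 1] within its
input frame, minimizing the mean squared error L = (1/n) sum (A_j - Y_j)^2
with the Adadelta optimizer.  Defaults follow the study protocol: dropout
50%, 50 epochs, batch size 32, and five-fold cross-validation with an 8:2
train:test split.

Augmentation: horizontal flipping (valid for every order, since lateral
radiographs occur in both left- and right-facing acquisitions) transforms
images and labels together and swaps anterior/posterior corner labels;
rotation and scaling about the crop centre are used for the third-order
models only, reflecting the variation of vertebral pose and size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .models import NetworkModel
from .nn import Adadelta, mse_grad, mse_loss

__all__ = [
    "TrainingConfig", "TrainingSample", "mse_loss", "augment_sample",
    "standardize", "train_model", "cross_validate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 32
    dropout: float = 0.5
    optimizer: str = "adadelta"
    folds: int = 5              # five folds -> 8:2 train:test split
    seed: int = 0
    hflip: bool = True
    rotate_range_deg: float = 15.0   # third-order augmentation only
    scale_range: tuple[float, float] = (0.9, 1.1)
    fold_ratio_bound: float = 20.0   # max/min fold-error ratio sanity bound

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class TrainingSample:
    """One model-sized grey crop and its flat normalized label vector
    (x1, y1, x2, y2, ...) in units of the crop width/height."""

    image: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        if self.label.ndim != 1 or self.label.size % 2:
            raise ValueError("label must be a flat (x, y, ...) vector")


def standardize(image: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-variance normalization of a single crop."""
    img = np.asarray(image, dtype=np.float32)
    std = float(img.std())
    return (img - img.mean()) / (std if std > 1e-6 else 1.0)


def augment_sample(
    sample: TrainingSample,
    op: str,
    *,
    angle_deg: float = 0.0,
    scale_factor: float = 1.0,
    pair_slots: tuple[tuple[int, int], ...] = (),
) -> TrainingSample | None:
    """Apply one augmentation op, transforming image and labels together.

    ``hflip`` mirrors the crop and maps normalized x to (W-1-x_px)/W while
    swapping the anterior/posterior point pairs given in ``pair_slots``
    (pairs of point indices).  ``rotate`` / ``scale`` act about the crop
    centre.  Returns None (with a log entry) when a transformed label falls
    outside [-0.1, 1.1].
    """
    h, w = sample.image.shape
    pts = sample.label.reshape(-1, 2).astype(float).copy()

    if op == "hflip":
        img = sample.image[:, ::-1].copy()
        pts[:, 0] = (w - 1) / w - pts[:, 0]
        for i, j in pair_slots:
            pts[[i, j]] = pts[[j, i]]
    elif op in ("rotate", "scale"):
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        if op == "rotate":
            # image rotated about its centre; labels follow the same map
            a = np.radians(angle_deg)
            rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
            img = ndimage.rotate(sample.image, angle_deg, reshape=False,
                                 order=1, mode="nearest")
            px = pts * [w, h] - [cx, cy]
            pts = (px @ rot.T + [cx, cy]) / [w, h]
        else:
            k = float(scale_factor)
            mat = np.array([[1.0 / k, 0.0], [0.0, 1.0 / k]])
            off = np.array([cy - cy / k, cx - cx / k])
            img = ndimage.affine_transform(sample.image, mat, offset=off,
                                           order=1, mode="nearest")
            px = pts * [w, h]
            pts = (np.stack([cx + k * (px[:, 0] - cx),
                             cy + k * (px[:, 1] - cy)], axis=1)) / [w, h]
    else:
        raise ValueError(f"unknown augmentation op {op!r}")

    flat = pts.reshape(-1)
    if np.any(flat < -0.1) or np.any(flat > 1.1):
        log.warning("augmentation %s rejected: label outside [-0.1, 1.1]", op)
        return None
    return TrainingSample(image=img, label=np.clip(flat, 0.0, 1.0))


def _to_arrays(samples: list[TrainingSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([standardize(s.image) for s in samples])[..., None]
    y = np.stack([s.label for s in samples]).astype(np.float32)
    return x, y


def train_model(
    model: NetworkModel,
    samples: list[TrainingSample],
    cfg: TrainingConfig,
    val_samples: list[TrainingSample] | None = None,
) -> tuple[NetworkModel, dict[str, list[float]]]:
    """Train one model in place; returns it with per-epoch loss history."""
    if not samples:
        raise ValueError("empty training set")
    x, y = _to_arrays(samples)
    if y.shape[1] != model.arch.output_units:
        raise ValueError(f"label length {y.shape[1]} does not match model "
                         f"output_units {model.arch.output_units}")
    xv = yv = None
    if val_samples:
        xv, yv = _to_arrays(val_samples)

    from . import nn as _nn
    for layer in model.net.layers:  # config owns the dropout rate
        if isinstance(layer, _nn.Dropout):
            layer.rate = cfg.dropout

    rng = np.random.default_rng(cfg.seed)
    opt = Adadelta(model.net)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model.net.forward(x[idx], train=True)
            loss = mse_loss(out, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}")
            model.net.backward(mse_grad(out, y[idx]).astype(np.float32))
            opt.step()
            total += loss * len(idx)
        history["train_loss"].append(total / n)
        if xv is not None:
            history["val_loss"].append(mse_loss(model.net.forward(xv), yv))
        model.training_meta["epochs_completed"] = epoch + 1
    return model, history


def _landmark_error_px(model: NetworkModel, samples: list[TrainingSample]) -> float:
    x, y = _to_arrays(samples)
    pred = model.net.forward(x)
    h, w = samples[0].image.shape
    d = (pred - y).reshape(len(samples), -1, 2) * [w, h]
    return float(np.mean(np.hypot(d[..., 0], d[..., 1])))


def cross_validate(
    samples: list[TrainingSample],
    cfg: TrainingConfig,
    model_factory,
) -> list[dict[str, float]]:
    """Seeded k-fold cross-validation (default 5 folds, i.e. 8:2 splits).

    ``model_factory(fold_seed)`` must return a fresh model.  Returns one
    record per fold with validation loss and mean landmark error (pixels);
    raises if the max/min fold-error ratio exceeds ``cfg.fold_ratio_bound``.
    """
    n = len(samples)
    if n < cfg.folds:
        raise ValueError("dataset smaller than number of folds")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cfg.folds)
    records: list[dict[str, float]] = []
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        model = model_factory(cfg.seed + k)
        model, hist = train_model(
            model, [samples[i] for i in train_idx], cfg,
            val_samples=[samples[i] for i in test_idx])
        records.append({
            "fold": k,
            "train_size": int(train_idx.size),
            "test_size": int(test_idx.size),
            "val_loss": hist["val_loss"][-1],
            "landmark_error_px": _landmark_error_px(
                model, [samples[i] for i in test_idx]),
        })
    errs = [r["val_loss"] for r in records]
    if min(errs) > 0 and max(errs) / min(errs) > cfg.fold_ratio_bound:
        raise RuntimeError(
            f"fold-error ratio {max(errs) / min(errs):.1f} exceeds bound "
            f"{cfg.fold_ratio_bound}")
    return records
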