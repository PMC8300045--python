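"""Loss functions and the training regime.

The multi-task objective is the plain sum of a categorical cross-entropy
per segmentation branch and the batch-averaged per-image RMSE of the depth
branch.  Optimization is Adam (alpha 0.001, beta1 0.9, beta2 0.999,
eps 1e-7) with a fixed number of optimizer steps per epoch, shuffling
between epochs, and early stopping on validation loss with best-weight
restoration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import io_cli
from .network import ModelHandle, Predictions, get_weight_state, set_weight_state, softmax
from .scene_synth import StereoFrame

log = logging.getLogger("binoseg.training")

PROB_FLOOR = 1e-7   # numerical floor for log-probabilities


# --------------------------------------------------------------------------
# Configuration / history
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    max_epochs: int = 150
    batch_size: int = 8
    steps_per_epoch: int = 32
    early_stop_patience: int = 15
    shuffle_between_epochs: bool = True
    augmentation: Literal["none", "vertical_flip"] = "none"
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "beta1", "beta2", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")
        if self.batch_size < 1 or self.steps_per_epoch < 1:
            raise ValueError("batch_size and steps_per_epoch must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch loss components; total is always their exact sum."""

    columns = ("train_ce_left", "train_ce_right", "train_depth_rmse",
               "train_total", "val_ce_left", "val_ce_right",
               "val_depth_rmse", "val_total")

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False
    seed: int = 0

    def log_epoch(self, train_parts, val_parts) -> None:
        row = {}
        for prefix, parts in (("train", train_parts), ("val", val_parts)):
            ce_l, ce_r, rmse = parts
            row[f"{prefix}_ce_left"] = ce_l
            row[f"{prefix}_ce_right"] = ce_r
            row[f"{prefix}_depth_rmse"] = rmse
            row[f"{prefix}_total"] = ce_l + ce_r + rmse
        self.epochs.append(row)

    @property
    def val_totals(self) -> list[float]:
        return [e["val_total"] for e in self.epochs]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.epochs)
        df.index.name = "epoch"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------


def categorical_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                              class_count: int) -> float:
    """Mean over all pixels (and any batch axis) of -log p(true class)."""
    p_true = np.take_along_axis(
        probs, labels[..., None].astype(np.intp), axis=-1)[..., 0]
    return float(-np.log(np.clip(p_true, PROB_FLOOR, 1.0)).mean())


def depth_rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Per-image RMSE, averaged over the batch axis if present."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape[-1] == 1:
        pred = pred[..., 0]
    if pred.shape != truth.shape:
        raise ValueError(f"depth shapes differ: {pred.shape} vs {truth.shape}")
    sq = (pred - truth) ** 2
    if pred.ndim == 2:
        return float(np.sqrt(sq.mean()))
    return float(np.sqrt(sq.mean(axis=(1, 2))).mean())


def compute_losses(preds: Predictions, truth: StereoFrame
                   ) -> tuple[float, float, float, float]:
    """(ce_left, ce_right, depth_rmse, total); absent branches contribute 0.

    The right-segmentation and depth terms are dropped for variants lacking
    those branches; the total is always the exact sum of the remaining
    components.
    """
    class_count = preds.left_seg_probs.shape[-1]
    ce_l = categorical_cross_entropy(preds.left_seg_probs, truth.left_labels,
                                     class_count)
    ce_r = 0.0
    if preds.right_seg_probs is not None:
        ce_r = categorical_cross_entropy(preds.right_seg_probs,
                                         truth.right_labels, class_count)
    rmse = 0.0
    if preds.depth_map is not None:
        rmse = depth_rmse(preds.depth_map, truth.depth_left)
    return ce_l, ce_r, rmse, ce_l + ce_r + rmse


# --------------------------------------------------------------------------
# Optimizer
# --------------------------------------------------------------------------


class Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.params = [p for p in params if p.trainable]
        self.cfg = cfg
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * p.grad
            v *= c.beta2
            v += (1 - c.beta2) * p.grad ** 2
            p.value -= (c.alpha * (m / bc1)
                        / (np.sqrt(v / bc2) + c.epsilon)).astype(np.float32)


# --------------------------------------------------------------------------
# Early stopping
# --------------------------------------------------------------------------


def early_stop_scan(val_losses, patience: int) -> tuple[int, int, bool]:
    """Replay the early-stopping rule over a validation-loss sequence.

    Any strict decrease below the best loss so far counts as improvement;
    training stops after ``patience`` consecutive epochs without one.
    Returns (best_epoch, last_epoch_run, stopped_early), all 0-based.
    """
    best = np.inf
    best_epoch = -1
    since = 0
    for i, v in enumerate(val_losses):
        if v < best:
            best = v
            best_epoch = i
            since = 0
        else:
            since += 1
        if since >= patience:
            return best_epoch, i, True
    return best_epoch, len(val_losses) - 1, False


# --------------------------------------------------------------------------
# Data handling
# --------------------------------------------------------------------------


class FrameArrays:
    """Dataset frames stacked into contiguous float32/int arrays."""

    def __init__(self, frames):
        frames = list(frames)
        if not frames:
            raise ValueError("empty dataset")
        self.left = np.stack([f.left_rgb for f in frames]).astype(np.float32)
        self.right = np.stack([f.right_rgb for f in frames]).astype(np.float32)
        self.left_labels = np.stack([f.left_labels for f in frames])
        self.right_labels = np.stack([f.right_labels for f in frames])
        self.depth = np.stack([f.depth_left for f in frames]).astype(np.float32)
        self.depth_right = np.stack(
            [f.depth_right for f in frames]).astype(np.float32)

    def __len__(self) -> int:
        return self.left.shape[0]

    @classmethod
    def from_manifest(cls, manifest_path, split: str | None):
        return cls(io_cli.read_dataset(manifest_path, split=split))


def _one_hot(labels: np.ndarray, class_count: int) -> np.ndarray:
    return np.eye(class_count, dtype=np.float32)[labels]


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------


def _losses_and_grads(model: ModelHandle, feeds, labels_l, labels_r, depth_t,
                      want_grads: bool):
    """Forward in the requested mode; optionally seed output gradients."""
    cfg = model.config
    roles = model.output_names
    outs = model.graph.forward(feeds, list(roles.values()),
                               training=want_grads)
    n, h, wdt = labels_l.shape[0], cfg.input_height, cfg.input_width
    grads = {}

    logits_l = outs[roles["left_seg"]]
    probs_l = softmax(logits_l)
    ce_l = categorical_cross_entropy(probs_l, labels_l, cfg.class_count)
    if want_grads:
        y = _one_hot(labels_l, cfg.class_count)
        grads[roles["left_seg"]] = (probs_l - y) / (n * h * wdt)

    ce_r = 0.0
    if "right_seg" in roles:
        logits_r = outs[roles["right_seg"]]
        probs_r = softmax(logits_r)
        ce_r = categorical_cross_entropy(probs_r, labels_r, cfg.class_count)
        if want_grads:
            y = _one_hot(labels_r, cfg.class_count)
            grads[roles["right_seg"]] = (probs_r - y) / (n * h * wdt)

    rmse = 0.0
    if "depth" in roles:
        pred = outs[roles["depth"]][..., 0]
        err = pred - depth_t
        per_image = np.sqrt((err ** 2).mean(axis=(1, 2)))
        rmse = float(per_image.mean())
        if want_grads:
            denom = np.maximum(per_image, 1e-8)[:, None, None]
            grads[roles["depth"]] = (err / (denom * h * wdt * n))[..., None]
    parts = (ce_l, ce_r, rmse)
    return parts, {k: v.astype(np.float32) for k, v in grads.items()}


def _epoch_eval(model: ModelHandle, data: FrameArrays, batch: int):
    parts_sum = np.zeros(3)
    n = len(data)
    nb = 0
    binocular = model.config.variant != "monocular_unet"
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        feeds = {"left_rgb": data.left[sl]}
        if binocular:
            feeds["right_rgb"] = data.right[sl]
        parts, _ = _losses_and_grads(model, feeds, data.left_labels[sl],
                                     data.right_labels[sl], data.depth[sl],
                                     want_grads=False)
        w = sl.stop - sl.start
        parts_sum += np.asarray(parts) * w
        nb += w
    return tuple(parts_sum / nb)


def train_network(model: ModelHandle, train_data, val_data, cfg: TrainConfig,
                  train_split: str | None = "train",
                  val_split: str | None = "val"
                  ) -> tuple[ModelHandle, TrainHistory]:
    """Train ``model`` in place and return it frozen at the best epoch.

    ``train_data`` / ``val_data`` are dataset manifests (paths) or
    ``FrameArrays``.  One master seed (``cfg.seed``) drives shuffling and
    augmentation.  Training halts at ``max_epochs`` or once validation
    total loss has not strictly improved for ``early_stop_patience``
    consecutive epochs; the returned model carries the best-epoch weights.
    """
    cfg.validate()
    if not isinstance(train_data, FrameArrays):
        train_data = FrameArrays.from_manifest(train_data, train_split)
    if not isinstance(val_data, FrameArrays):
        val_data = FrameArrays.from_manifest(val_data, val_split)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg)
    history = TrainHistory(seed=cfg.seed)
    binocular = model.config.variant != "monocular_unet"

    n = len(train_data)
    order = np.arange(n)
    cursor = n  # force an initial (re)shuffle
    best_state = None
    best_val = np.inf
    since_improve = 0

    for epoch in range(cfg.max_epochs):
        parts_sum = np.zeros(3)
        for _step in range(cfg.steps_per_epoch):
            if cursor + cfg.batch_size > n:
                if cfg.shuffle_between_epochs or cursor >= n:
                    order = rng.permutation(n)
                cursor = 0
            idx = order[cursor:cursor + cfg.batch_size]
            cursor += cfg.batch_size
            xl = train_data.left[idx]
            xr = train_data.right[idx]
            ll = train_data.left_labels[idx]
            lr = train_data.right_labels[idx]
            dep = train_data.depth[idx]
            if cfg.augmentation == "vertical_flip":
                flip = rng.random(len(idx)) < 0.5
                xl = np.where(flip[:, None, None, None], xl[:, ::-1], xl)
                xr = np.where(flip[:, None, None, None], xr[:, ::-1], xr)
                ll = np.where(flip[:, None, None], ll[:, ::-1], ll)
                lr = np.where(flip[:, None, None], lr[:, ::-1], lr)
                dep = np.where(flip[:, None, None], dep[:, ::-1], dep)
            feeds = {"left_rgb": xl}
            if binocular:
                feeds["right_rgb"] = xr
            parts, grads = _losses_and_grads(model, feeds, ll, lr, dep,
                                             want_grads=True)
            total = sum(parts)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {parts}")
            parts_sum += np.asarray(parts)
            opt.zero_grad()
            model.graph.backward(grads)
            opt.step()
        train_parts = tuple(parts_sum / cfg.steps_per_epoch)
        val_parts = _epoch_eval(model, val_data, cfg.batch_size)
        history.log_epoch(train_parts, val_parts)
        val_total = history.epochs[-1]["val_total"]
        if not np.isfinite(val_total):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        if val_total < best_val:
            best_val = val_total
            best_state = get_weight_state(model)
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
        log.info("epoch %d: train %.4f val %.4f (best %.4f)",
                 epoch, history.epochs[-1]["train_total"], val_total, best_val)
        if since_improve >= cfg.early_stop_patience:
            history.stopped_early = True
            break
    if best_state is not None:
        set_weight_state(model, best_state)
    return model, history
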