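"""Losses, overlap metrics, the training protocol, and evaluation reporting.

Training optimizes the smoothed soft Dice loss with the smoothed Jaccard
distance logged as an auxiliary (optionally folded into the objective with a
configurable weight), under Adam with ReduceLROnPlateau (factor 0.2,
patience 5) monitoring validation Dice, early stopping (patience 20),
best-validation checkpointing plus periodic checkpoints every 5 epochs, and
resumable 50-epoch sessions up to 150 epochs total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn as nn
from .models import ModelGraph

# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _check_shapes(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def dice_coefficient(pred, truth) -> float:
    """2|A∩B| / (|A|+|B|) between binary masks; both-empty -> 1.0."""
    pred, truth = _check_shapes(pred, truth)
    a, b = pred.astype(bool), truth.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(pred, truth) -> float:
    """|A∩B| / |A∪B| between binary masks; both-empty -> 1.0."""
    pred, truth = _check_shapes(pred, truth)
    a, b = pred.astype(bool), truth.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def binary_accuracy(pred, truth, threshold: float = 0.5) -> float:
    """Pixel fraction where thresholded probability equals truth; ties (=0.5)
    count as positive."""
    pred, truth = _check_shapes(pred, truth)
    hard = pred >= threshold
    return float((hard == truth.astype(bool)).mean())


# ---------------------------------------------------------------------------
# Losses (NumPy versions for reporting; Tensor versions for training)
# ---------------------------------------------------------------------------


def soft_dice_loss(pred, truth, smooth: float = 1.0) -> float:
    """1 - (2 Σpt + s)/(Σp + Σt + s) on probability grids."""
    pred, truth = _check_shapes(pred, truth)
    p, t = pred.astype(np.float64), truth.astype(np.float64)
    inter = (p * t).sum()
    return float(1.0 - (2.0 * inter + smooth) / (p.sum() + t.sum() + smooth))


def jaccard_distance(pred, truth, smooth: float = 100.0, scaled: bool = True) -> float:
    """Smoothed Jaccard distance: (1 - (I+s)/(U-I+s)) * s with I = Σpt,
    U = Σp + Σt; the x`s` scaling matches the common reference formulation
    behind the "smooth factor = 100" convention (set scaled=False for the
    plain complement)."""
    pred, truth = _check_shapes(pred, truth)
    p, t = pred.astype(np.float64), truth.astype(np.float64)
    inter = (p * t).sum()
    total = p.sum() + t.sum()
    jd = 1.0 - (inter + smooth) / (total - inter + smooth)
    return float(jd * smooth if scaled else jd)


def _soft_dice_loss_t(pred: nn.Tensor, truth: np.ndarray, smooth: float = 1.0) -> nn.Tensor:
    t = nn.Tensor(truth.astype(np.float32))
    inter = nn.tsum(nn.mul(pred, t))
    num = nn.add(nn.mul(inter, nn.Tensor(2.0)), nn.Tensor(smooth))
    den = nn.add(nn.add(nn.tsum(pred), nn.tsum(t)), nn.Tensor(smooth))
    return nn.sub(nn.Tensor(1.0), nn.div(num, den))


def _jaccard_distance_t(pred: nn.Tensor, truth: np.ndarray, smooth: float = 100.0) -> nn.Tensor:
    t = nn.Tensor(truth.astype(np.float32))
    inter = nn.tsum(nn.mul(pred, t))
    total = nn.add(nn.tsum(pred), nn.tsum(t))
    num = nn.add(inter, nn.Tensor(smooth))
    den = nn.add(nn.sub(total, inter), nn.Tensor(smooth))
    jd = nn.sub(nn.Tensor(1.0), nn.div(num, den))
    return nn.mul(jd, nn.Tensor(smooth))


# ---------------------------------------------------------------------------
# Configuration and reports
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 150
    session_epochs: int = 50
    plateau_factor: float = 0.2
    plateau_patience: int = 5
    early_stop_patience: int = 20
    checkpoint_period: int = 5
    dice_smooth: float = 1.0
    jaccard_smooth: float = 100.0
    jaccard_weight: float = 0.0  # optional weighted sum of the two losses
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0,1)")
        for name in ("batch_size", "learning_rate", "max_epochs", "plateau_patience",
                     "early_stop_patience", "checkpoint_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetricReport:
    per_slice: pd.DataFrame
    dice: float
    iou: float
    binary_accuracy: float
    aggregation: str = "mean_per_slice"

    def to_json(self) -> str:
        return json.dumps(
            {
                "dice": self.dice,
                "iou": self.iou,
                "binary_accuracy": self.binary_accuracy,
                "aggregation": self.aggregation,
                "n_slices": int(len(self.per_slice)),
            },
            indent=2,
        )


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict
    best_val_dice: float
    best_epoch: int
    stopped_early: bool
    checkpoints: list


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _as_arrays(dataset):
    """Accept (images, masks) arrays or a list of SlicePair."""
    if isinstance(dataset, tuple):
        images, masks = dataset
        return np.asarray(images, dtype=np.float32), np.asarray(masks)
    images = np.stack([p.image for p in dataset]).astype(np.float32)
    masks = np.stack([p.mask for p in dataset])
    return images, masks


def train(
    model: ModelGraph,
    train_set,
    val_set,
    config: TrainConfig,
    out_dir=None,
    augment_fn=None,
    start_epoch: int = 0,
    _state=None,
) -> TrainResult:
    """Train `model`, returning history plus the best-validation-Dice weights.

    The monitored quantity is validation Dice (maximized).  The learning
    rate is multiplied by `plateau_factor` after `plateau_patience`
    consecutive non-improving epochs; training halts after
    `early_stop_patience` such epochs.  The best checkpoint is retained and
    a periodic checkpoint is written every `checkpoint_period` epochs (and
    at every `session_epochs` boundary so a run can resume).
    """
    tr_images, tr_masks = _as_arrays(train_set)
    if len(tr_images) == 0:
        raise ValueError("empty training set")
    va_images, va_masks = _as_arrays(val_set)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    if _state is not None:  # resume
        opt.m, opt.v, opt.t = _state["m"], _state["v"], _state["t"]
        opt.lr = _state["lr"]

    best_state = model.state_dict()
    best_val = -np.inf
    best_epoch = -1
    plateau_wait = 0
    stop_wait = 0
    stopped_early = False
    rows = []
    checkpoints = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    n = len(tr_images)
    for epoch in range(start_epoch, config.max_epochs):
        order = rng.permutation(n)
        losses, aux_losses = [], []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = tr_images[idx]
            yb = tr_masks[idx]
            if augment_fn is not None:
                xb, yb = augment_fn(xb, yb, rng)
            pred = model(nn.Tensor(xb), training=True)
            yb4 = yb.reshape(yb.shape + (1,)) if yb.ndim == 3 else yb
            loss = _soft_dice_loss_t(pred, yb4, config.dice_smooth)
            aux = _jaccard_distance_t(pred, yb4, config.jaccard_smooth)
            objective = loss
            if config.jaccard_weight > 0:
                objective = nn.add(loss, nn.mul(aux, nn.Tensor(config.jaccard_weight)))
            opt.zero_grad()
            objective.backward()
            opt.step()
            losses.append(float(loss.data))
            aux_losses.append(float(aux.data))
        probs = model.predict(va_images)[..., 0]
        val_dice = float(
            np.mean([dice_coefficient(p >= config.threshold, m) for p, m in zip(probs, va_masks)])
        )
        val_iou = float(
            np.mean([iou(p >= config.threshold, m) for p, m in zip(probs, va_masks)])
        )
        rows.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "aux_loss": float(np.mean(aux_losses)),
                "val_dice": val_dice,
                "val_iou": val_iou,
                "lr": opt.lr,
            }
        )
        improved = val_dice > best_val
        if improved:
            best_val = val_dice
            best_epoch = epoch + 1
            best_state = model.state_dict()
            plateau_wait = 0
            stop_wait = 0
            if out is not None:
                _save_checkpoint(model, out / "best.npz", out / "best_shapes.json")
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                plateau_wait = 0
        if (epoch + 1) % config.checkpoint_period == 0:
            checkpoints.append(epoch + 1)
            if out is not None:
                _save_checkpoint(
                    model, out / f"epoch_{epoch + 1:04d}.npz", out / f"epoch_{epoch + 1:04d}_shapes.json"
                )
        if stop_wait >= config.early_stop_patience:
            stopped_early = True
            break
        if (epoch + 1) % config.session_epochs == 0 and out is not None:
            _save_checkpoint(model, out / "session.npz", out / "session_shapes.json")

    history = pd.DataFrame(rows)
    if out is not None:
        history.to_csv(out / "history.csv", index=False)
    return TrainResult(history, best_state, float(best_val), best_epoch, stopped_early, checkpoints)


def _save_checkpoint(model: ModelGraph, npz_path, shapes_path):
    state = model.state_dict()
    np.savez(npz_path, **state)
    Path(shapes_path).write_text(
        json.dumps({k: list(np.asarray(v).shape) for k, v in state.items()}, indent=2)
    )


def load_checkpoint(model: ModelGraph, npz_path):
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


class OracleModel:
    """Reference model that emits the ground-truth mask it is handed.

    Used to validate the metric/reporting path (Dice = IoU = 1 by
    construction) and as a stand-in predictor in pipeline smoke runs.
    """

    def __init__(self, masks_by_key=None):
        self._masks = masks_by_key or {}
        self._truth = None

    def bind_truth(self, masks: np.ndarray):
        self._truth = np.asarray(masks)
        return self

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        if self._truth is None:
            raise RuntimeError("OracleModel.predict requires bind_truth() first")
        t = self._truth.astype(np.float32)
        return t.reshape(t.shape + (1,)) if t.ndim == 3 else t


def evaluate(model, dataset, threshold: float = 0.5, out_dir=None) -> MetricReport:
    """Per-slice Dice/IoU/accuracy at the given threshold plus mean aggregates."""
    images, masks = _as_arrays(dataset)
    if isinstance(model, OracleModel):
        model.bind_truth(masks)
    probs = model.predict(images)[..., 0]
    rows = []
    for i, (p, m) in enumerate(zip(probs, masks)):
        hard = p >= threshold
        rows.append(
            {
                "slice": i,
                "dice": dice_coefficient(hard, m),
                "iou": iou(hard, m),
                "binary_accuracy": binary_accuracy(p, m, threshold),
            }
        )
    per_slice = pd.DataFrame(rows)
    report = MetricReport(
        per_slice=per_slice,
        dice=float(per_slice["dice"].mean()),
        iou=float(per_slice["iou"].mean()),
        binary_accuracy=float(per_slice["binary_accuracy"].mean()),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_slice.to_csv(out / "metrics_per_slice.csv", index=False)
        (out / "metrics.json").write_text(report.to_json())
    return report
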