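"""Training loop and count-evaluation metrics.

The network is fitted with Adam on pixel-mean squared error between the
predicted density (head channel 0) and the ground-truth density map, batch
size 8 and learning rate 0.001 by default, for at most 200 epochs with
early stopping after 20 epochs without validation improvement and
restoration of the best weights.  Metrics follow the standard definitions:

    MAE  = (1/n) sum |y_i - yhat_i|
    MSE  = (1/n) sum (y_i - yhat_i)^2
    MAPE = (100/n) sum |y_i - yhat_i| / y_i      (0-100 percent scale)
    RMSE = sqrt(MSE)
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .backprop import Adam
from .errors import ValidationError
from .sorghum_net import NetworkHandle

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MetricsReport", "train", "evaluate_counts", "write_history"]


@dataclass
class TrainConfig:
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 8
    learning_rate: float = 0.001
    seed: int = 0
    min_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")


@dataclass
class MetricsReport:
    n: int
    mae: float
    mse: float
    mape: float
    rmse: float
    r2: Optional[float] = None

    def as_dict(self) -> dict:
        out = {"n": self.n, "mae": self.mae, "mse": self.mse,
               "mape": self.mape, "rmse": self.rmse}
        if self.r2 is not None:
            out["r2"] = self.r2
        return out


def _as_pairs(pairs, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    x, y = pairs
    x = np.asarray(x, dtype=dtype)
    y = np.asarray(y, dtype=dtype)
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValidationError(f"images must be (n, H, W, 3), got {x.shape}")
    if y.shape != x.shape[:3]:
        raise ValidationError(
            f"density maps {y.shape} do not match images {x.shape[:3]}"
        )
    return x, y


def _epoch_loss(handle: NetworkHandle, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> float:
    """Pixel-mean MSE in eval mode (running batch-norm statistics)."""
    total, count = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        pred = handle.forward(xb, train=False)[..., 0]
        total += float(((pred - yb) ** 2).sum())
        count += yb.size
    return total / count


def train(handle: NetworkHandle, train_pairs, val_pairs,
          cfg: TrainConfig | None = None) -> tuple[NetworkHandle, list[dict]]:
    """Fit the network; returns the handle (best weights restored) and a
    per-epoch history of train/validation loss.

    ``train_pairs`` / ``val_pairs`` are ``(images, density_maps)`` with
    images normalized to [0, 1].  Training is deterministic for a fixed
    seed under single-threaded BLAS.
    """
    cfg = cfg or TrainConfig()
    dtype = handle.net.head.w.value.dtype
    xt, yt = _as_pairs(train_pairs, dtype)
    xv, yv = _as_pairs(val_pairs, dtype)
    if handle.arch.output_scale != 1.0:
        scale = np.asarray(handle.arch.output_scale, dtype=dtype)
        yt = yt * scale
        yv = yv * scale
    if len(xt) == 0:
        raise ValidationError("empty training set")
    if len(xv) == 0:
        raise ValidationError("empty validation set")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(handle.net.params(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_epoch = -1
    best_weights: list[np.ndarray] | None = None
    stale = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(xt))
        running, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = xt[idx], yt[idx]
            pred = handle.forward(xb, train=True)
            diff = pred[..., 0] - yb
            loss = float((diff ** 2).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {i // cfg.batch_size} (lr={cfg.learning_rate})"
                )
            dpred = np.zeros_like(pred)
            dpred[..., 0] = 2.0 * diff / diff.size
            handle.net.backward(dpred)
            opt.step()
            opt.zero_grad()
            running += loss * len(idx)
            seen += len(idx)
        train_loss = running / seen
        val_loss = _epoch_loss(handle, xv, yv, cfg.batch_size)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train %.3e val %.3e", epoch, train_loss, val_loss)

        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_epoch = epoch
            best_weights = [p.value.copy() for p in handle.net.params()]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
                break

    if best_weights is not None:
        for p, w in zip(handle.net.params(), best_weights):
            p.value = w
    return handle, history


def evaluate_counts(y_obs: Sequence[float], y_pred: Sequence[float],
                    with_mape: bool = True) -> MetricsReport:
    """Count-level error metrics between observed and predicted grain
    numbers.  MAPE requires strictly positive observed values."""
    yo = np.asarray(y_obs, dtype=np.float64)
    yp = np.asarray(y_pred, dtype=np.float64)
    if yo.shape != yp.shape or yo.ndim != 1:
        raise ValidationError(
            f"observed and predicted must be equal-length 1-D, got {yo.shape} vs {yp.shape}"
        )
    if yo.size == 0:
        raise ValidationError("empty metric input")
    err = yo - yp
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    rmse = float(np.sqrt(mse))
    if with_mape:
        zero = np.flatnonzero(yo == 0)
        if zero.size:
            raise ValidationError(
                f"MAPE undefined: observed value is zero at indices {zero.tolist()[:20]}"
            )
        mape = float((np.abs(err) / np.abs(yo)).mean() * 100.0)
    else:
        mape = float("nan")
    return MetricsReport(n=int(yo.size), mae=mae, mse=mse, mape=mape, rmse=rmse)


def write_history(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
        writer.writeheader()
        writer.writerows(history)
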