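"""Optimization protocol: Adam, poly learning-rate decay, the epoch
loop with seeded shuffling and deep supervision, best-checkpoint
selection by validation mean DSC, and slice-wise volume prediction.

The learning-rate schedule is the poly decay

    lr(epoch) = init_lr * (1 - epoch / n_epoch) ** power

stepped once per epoch (the schedule is defined in epochs).  Defaults:
init_lr 1e-3, power 0.9, n_epoch 100, batch size 24, Adam with the
standard moment coefficients (0.9, 0.999) and no weight decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .autograd import Tensor
from .evaluation import evaluate_cohort
from .losses import LossWeights, bce_loss, dice_loss, mixed_loss
from .model import CrossAttentionUNet, ModelConfig
from .preprocessing import SliceSample

__all__ = ["TrainConfig", "TrainResult", "Adam", "poly_learning_rate",
           "train_model", "predict_volume", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class TrainConfig:
    init_lr: float = 1e-3
    power: float = 0.9
    n_epoch: int = 100
    batch_size: int = 24
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.init_lr <= 0 or self.power <= 0:
            raise ValueError("init_lr and power must be positive")
        if self.n_epoch < 1 or self.batch_size < 1:
            raise ValueError("n_epoch and batch_size must be >= 1")


def poly_learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Poly decay evaluated at an integer epoch, 0 <= epoch < n_epoch."""
    if not 0 <= epoch < cfg.n_epoch:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.n_epoch})")
    return cfg.init_lr * (1.0 - epoch / cfg.n_epoch) ** cfg.power


class Adam:
    """Adam with bias correction; lr is mutable for scheduling."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    history: pd.DataFrame          # epoch, lr, train_loss, val_dsc
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_dsc: float
    model: CrossAttentionUNet

    def save_history(self, path: str | Path):
        self.history.to_csv(path, index=False)


def _stack_samples(samples: Sequence[SliceSample]):
    X = np.stack([s.image for s in samples])[:, None, :, :].astype(np.float32)
    Y = np.stack([s.mask for s in samples])[:, None, :, :].astype(np.float32)
    return X, Y


def train_model(train_samples: Sequence[SliceSample],
                val_volumes: Mapping[str, tuple[np.ndarray, np.ndarray]],
                model: CrossAttentionUNet,
                cfg: TrainConfig,
                verbose: bool = False) -> TrainResult:
    """Train on preprocessed slices; select the best epoch by validation
    mean 3D DSC.

    ``val_volumes`` maps subject id to a preprocessed (image, mask)
    volume pair; validation DSC comes from :func:`evaluate_cohort` on
    slice-wise predictions, the same metric path used at test time.
    """
    if len(train_samples) == 0:
        raise ValueError("training set is empty")
    X, Y = _stack_samples(train_samples)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.init_lr)
    deep = model.config.deep_supervision
    n = X.shape[0]
    rows = []
    best_state, best_epoch, best_val = None, -1, -np.inf

    for epoch in range(cfg.n_epoch):
        opt.lr = poly_learning_rate(epoch, cfg)
        model.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            outs = model(X[idx])
            target = Tensor(Y[idx])
            if deep:
                loss = mixed_loss(outs, target, cfg.loss_weights)
            else:
                loss = (dice_loss(outs[0], target, cfg.loss_weights.epsilon)
                        + bce_loss(outs[0], target))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        train_loss = float(np.mean(losses))

        val_dsc = np.nan
        if val_volumes:
            preds = {sid: predict_volume(model, img, cfg.batch_size)
                     for sid, (img, _) in val_volumes.items()}
            truths = {sid: msk for sid, (_, msk) in val_volumes.items()}
            val_dsc = evaluate_cohort(preds, truths).mean_dsc
            if val_dsc > best_val:
                best_val, best_epoch = val_dsc, epoch
                best_state = model.state_dict()
        rows.append({"epoch": epoch, "lr": opt.lr,
                     "train_loss": train_loss, "val_dsc": val_dsc})
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  "
                  f"loss {train_loss:.4f}  val_dsc {val_dsc:.4f}")

    if best_state is None:  # no validation set: keep the final weights
        best_state, best_epoch, best_val = model.state_dict(), cfg.n_epoch - 1, np.nan
    model.load_state_dict(best_state)
    return TrainResult(history=pd.DataFrame(rows), best_state=best_state,
                       best_epoch=best_epoch, best_val_dsc=float(best_val),
                       model=model)


def predict_volume(model: CrossAttentionUNet, image: np.ndarray,
                   batch_size: int = 16) -> np.ndarray:
    """Slice-by-slice inference (finest head only), restacked in order."""
    model.eval()
    n = image.shape[0]
    out = np.empty_like(image, dtype=np.float32)
    for start in range(0, n, batch_size):
        batch = image[start:start + batch_size][:, None, :, :].astype(np.float32)
        out[start:start + batch.shape[0]] = model.predict(batch)[:, 0]
    return out


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: CrossAttentionUNet,
                    extras: dict | None = None):
    """Weights + architecture config in one .npz (config as JSON)."""
    meta = {"model_config": model.config.to_dict(), "extras": extras or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[CrossAttentionUNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = CrossAttentionUNet(ModelConfig(**meta["model_config"]))
    model.load_state_dict(state)
    return model, meta.get("extras", {})
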