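"""Losses and the self-supervised training loop.

Training hides parts of complete samples behind artificial gaps and asks the
network to reconstruct them.  The loss is evaluated on the masked cells only
(L1 for point models, Gaussian negative log-likelihood for probabilistic
models); gaps are regenerated every epoch as data augmentation, while the
validation gaps are frozen once at the start so checkpoint selection tracks
a stationary criterion.  The parameters from the epoch with the lowest
validation RMSE are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyInputError, TrainingDivergedError
from .gaps import GapStats, MaskedSample, apply_gaps, apply_switch, sample_gaps
from .io import Sample
from .nn.autodiff import Tensor, no_grad
from .nn.models import _ImputerBase


@dataclass
class TrainConfig:
    """Optimization settings.

    Reference values: 1500 epochs, Adam at lr 1e-3 (1e-4 for the GRU, which
    is unstable at higher rates), exponential decay by 0.95 every 500 epochs,
    batches of at most 32, switch probability 0.1.
    """

    epochs: int = 1500
    lr: float = 1e-3
    scheduler_gamma: float = 0.95
    scheduler_step: int = 500
    batch_size: int = 32
    seed: int = 0
    switch_prob: float = 0.1
    n_missing: int = 1
    clip_grad: float | None = None

    def __post_init__(self) -> None:
        for name in ("epochs", "lr", "scheduler_gamma", "scheduler_step",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0


# ---------------------------------------------------------------------------
# losses — Tensor-aware for training, plain ndarray for evaluation


def _expand_mask(gap_mask: np.ndarray, D: int) -> np.ndarray:
    return np.repeat(gap_mask[..., None], D, axis=-1)


def masked_l1_loss(pred_mean, target: np.ndarray, gap_mask: np.ndarray):
    """Mean absolute deviation over the masked coordinates only."""
    n = int(gap_mask.sum())
    if n == 0:
        raise EmptyInputError("masked L1 loss needs at least one masked cell")
    D = target.shape[-1]
    m = _expand_mask(gap_mask, D)
    if isinstance(pred_mean, Tensor):
        dt = pred_mean.data.dtype
        diff = (pred_mean - Tensor(target.astype(dt))).abs() * Tensor(m.astype(dt))
        return diff.sum() * (1.0 / (n * D))
    return float(np.abs(pred_mean - target)[m].sum() / (n * D))


def gaussian_nll_loss(mean, std, target: np.ndarray, gap_mask: np.ndarray):
    """Gaussian negative log-likelihood on masked coordinates:
    mean over masked cells of 0.5 log(2 pi sigma^2) + (x - mu)^2 / (2 sigma^2)."""
    n = int(gap_mask.sum())
    if n == 0:
        raise EmptyInputError("NLL loss needs at least one masked cell")
    D = target.shape[-1]
    m = _expand_mask(gap_mask, D)
    if isinstance(mean, Tensor):
        dt = mean.data.dtype
        target = target.astype(dt)
        mt = Tensor(m.astype(dt))
        # keep sigma fixed at 1 outside the mask so masked-out terms are
        # finite; they are zeroed by the mask anyway
        sig = std * mt + Tensor((1.0 - m).astype(dt))
        var = sig * sig
        nll = (0.5 * (var * (2.0 * math.pi)).log()
               + (mean - Tensor(target)) ** 2 / (2.0 * var)) * mt
        return nll.sum() * (1.0 / (n * D))
    std = np.asarray(std, dtype=np.float64)
    if not (std[m] > 0).all():
        raise ConfigError("std must be strictly positive on masked cells")
    r = (mean - target)[m]
    s = std[m]
    return float(np.mean(0.5 * np.log(2.0 * math.pi * s ** 2)
                         + r ** 2 / (2.0 * s ** 2)))


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - (self.lr * (m / b1t)
                               / (np.sqrt(v / b2t) + self.eps)).astype(p.data.dtype)


def scheduled_lr(base_lr: float, epoch: int, gamma: float, step: int) -> float:
    """lr * gamma ** floor(epoch / step)."""
    return base_lr * gamma ** (epoch // step)


# ---------------------------------------------------------------------------
# batching helpers


def _stack_masked(batch: list[MaskedSample]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    inputs = np.stack([m.input for m in batch])
    masks = np.stack([m.gap_mask for m in batch])
    targets = np.stack([m.target for m in batch])
    return inputs, masks, targets


def _val_rmse(model: _ImputerBase, inputs: np.ndarray, masks: np.ndarray,
              targets: np.ndarray, batch_size: int) -> float:
    """RMSE over masked keypoint-frames, normalized units."""
    sq_sum, n = 0.0, 0
    model.eval()
    with no_grad():
        for i in range(0, len(inputs), batch_size):
            mean, _ = model(inputs[i:i + batch_size], masks[i:i + batch_size])
            d2 = ((mean.data - targets[i:i + batch_size]) ** 2).sum(axis=-1)
            msk = masks[i:i + batch_size]
            sq_sum += float(d2[msk].sum())
            n += int(msk.sum())
    model.train()
    return math.sqrt(sq_sum / max(n, 1))


def make_masked_batch(samples: list[Sample], stats: GapStats,
                      n_missing, switch_prob: float,
                      rng: np.random.Generator) -> list[MaskedSample]:
    """Fresh gaps (and optional switches) for each sample.

    ``n_missing`` is a fixed count or a (lo, hi) range sampled uniformly per
    sample (simultaneously missing keypoints).
    """
    out = []
    for s in samples:
        if isinstance(n_missing, tuple):
            k = int(rng.integers(n_missing[0], n_missing[1] + 1))
        else:
            k = int(n_missing)
        gaps = sample_gaps(stats, k, s.length, rng)
        m = apply_gaps(s, gaps)
        if switch_prob > 0:
            m = apply_switch(m, switch_prob, rng)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# the loop


def train(model: _ImputerBase,
          train_samples: list[Sample],
          val_samples: list[Sample],
          cfg: TrainConfig,
          gap_stats: GapStats,
          verbose: bool = False) -> tuple[_ImputerBase, TrainHistory]:
    """Optimize ``model`` on complete, normalized samples.

    Per epoch: fresh artificial gaps per sample, optional switch
    augmentation, masked L1 (or NLL for probabilistic models), one Adam step
    per batch with the scheduled learning rate.  Validation RMSE is computed
    on gaps frozen at the start; the parameters of the best epoch are
    restored before returning.
    """
    if not train_samples or not val_samples:
        raise EmptyInputError("train and validation sets must be non-empty")
    for s in train_samples + val_samples:
        if not s.is_complete:
            raise ConfigError("training requires complete samples")
    rng = np.random.default_rng(cfg.seed)
    val_rng = np.random.default_rng(cfg.seed + 1)

    val_masked = make_masked_batch(val_samples, gap_stats, cfg.n_missing,
                                   0.0, val_rng)
    v_inputs, v_masks, v_targets = _stack_masked(val_masked)

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    history = TrainHistory()
    best_rmse = math.inf
    best_state = model.state_dict()
    model.train()

    n = len(train_samples)
    for epoch in range(cfg.epochs):
        lr = scheduled_lr(cfg.lr, epoch, cfg.scheduler_gamma, cfg.scheduler_step)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            batch = [train_samples[j] for j in order[i:i + cfg.batch_size]]
            masked = make_masked_batch(batch, gap_stats, cfg.n_missing,
                                       cfg.switch_prob, rng)
            inputs, masks, targets = _stack_masked(masked)
            mean, std = model(inputs, masks)
            if model.config.proba:
                loss = gaussian_nll_loss(mean, std, targets, masks)
            else:
                loss = masked_l1_loss(mean, targets, masks)
            loss_val = float(loss.data)
            if not math.isfinite(loss_val):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(lr={lr:g})")
            opt.zero_grad()
            loss.backward()
            if cfg.clip_grad is not None:
                total = math.sqrt(sum(float((p.grad ** 2).sum())
                                      for p in params if p.grad is not None))
                if total > cfg.clip_grad:
                    scale = cfg.clip_grad / (total + 1e-12)
                    for p in params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            epoch_loss += loss_val
            n_batches += 1
        rmse = _val_rmse(model, v_inputs, v_masks, v_targets, cfg.batch_size)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_rmse.append(rmse)
        history.lr.append(lr)
        if rmse < best_rmse:
            best_rmse = rmse
            history.best_epoch = epoch
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:4d}  loss {history.train_loss[-1]:.5f}  "
                  f"val_rmse {rmse:.5f}  lr {lr:g}")
    model.load_state_dict(best_state)
    model.eval()
    return model, history
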