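"""Imputation backbones: transformer encoder, bidirectional GRU and TCN.

All three map a zero-filled sample plus its binary gap mask to per-coordinate
imputations.  With ``proba=True`` the output head doubles and the model
predicts a mean and a standard deviation per coordinate (heteroscedastic
Gaussian); the raw scale is passed through a softplus with a 1e-4 floor so
the deviation is strictly positive.

The transformer treats each (frame, keypoint) pair as a token: the keypoint's
coordinates (with the mask bit concatenated) pass through one linear
projection shared across keypoints, and lookup-table embeddings of the time
index, the keypoint identity and the mask bit are summed onto it.  The GRU
consumes the flattened pose per frame (each keypoint contributing x, y, z and
the mask bit) through bidirectional recurrent layers.  The TCN stacks
residual blocks of two dilated causal convolutions (dilations 1, 2, 4, 8)
with ReLU and dropout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import ConfigError, ShapeError
from ..gaps import MaskedSample
from .autodiff import Tensor, no_grad
from .layers import (DTYPE, BiGRULayer, CausalConv1d, Dropout, Embedding,
                     LayerNorm, Linear, Module, TransformerEncoderLayer)

_STD_FLOOR = 1e-4


@dataclass
class ModelConfig:
    """Architecture hyperparameters plus the data shape (L, K, D).

    Reference sizes: transformer — 4 layers, model dim 128, 8 heads;
    GRU — 3 bidirectional layers, hidden 512, no dropout; TCN — 4 residual
    blocks, hidden 256, dropout 0.2, dilations 1/2/4/8.  The ``desk``
    presets in :func:`desk_config` shrink these for CPU-scale runs.
    """

    backbone: str = "transformer"
    proba: bool = False
    K: int = 8
    D: int = 3
    L: int = 60
    model_dim: int = 128
    n_layers: int | None = None
    n_heads: int = 8
    ff_dim: int | None = None
    hidden: int | None = None
    dropout: float | None = None
    n_missing_train: int = 1   # gap regime the model is trained for

    def __post_init__(self) -> None:
        if self.backbone not in ("transformer", "gru", "tcn"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.n_layers is None:
            self.n_layers = {"transformer": 4, "gru": 3, "tcn": 4}[self.backbone]
        if self.ff_dim is None:
            self.ff_dim = self.model_dim
        if self.hidden is None:
            self.hidden = {"transformer": 0, "gru": 512, "tcn": 256}[self.backbone]
        if self.dropout is None:
            self.dropout = {"transformer": 0.0, "gru": 0.0, "tcn": 0.2}[self.backbone]
        if self.backbone == "transformer" and self.model_dim % self.n_heads:
            raise ConfigError("model_dim must be divisible by n_heads")
        for name in ("K", "D", "L", "model_dim", "n_layers"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def desk_config(backbone: str, K: int, D: int, L: int = 60,
                proba: bool = False, **overrides) -> ModelConfig:
    """CPU-scale preset: small dims so a training finishes in minutes."""
    base = {"transformer": dict(model_dim=32, n_layers=2, n_heads=1, ff_dim=32),
            "gru": dict(n_layers=2, hidden=48),
            "tcn": dict(n_layers=3, hidden=48)}[backbone]
    base.update(overrides)
    return ModelConfig(backbone=backbone, proba=proba, K=K, D=D, L=L, **base)


@dataclass
class Prediction:
    """Per-coordinate imputed mean and optional standard deviation
    (normalized units)."""

    mean: np.ndarray              # (L, K, D) or (B, L, K, D)
    std: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.std is not None and not (self.std > 0).all():
            raise ValueError("std must be strictly positive")


class _ImputerBase(Module):
    config: ModelConfig

    def _split_head(self, out: Tensor, B: int) -> tuple[Tensor, Tensor | None]:
        c = self.config
        out = out.reshape(B, c.L, c.K, -1)
        mean = out[:, :, :, :c.D]
        if not c.proba:
            return mean, None
        std = out[:, :, :, c.D:].softplus() + _STD_FLOOR
        return mean, std

    def forward(self, inputs: np.ndarray, mask: np.ndarray
                ) -> tuple[Tensor, Tensor | None]:
        raise NotImplementedError

    def __call__(self, inputs: np.ndarray, mask: np.ndarray):
        c = self.config
        if inputs.shape[1:] != (c.L, c.K, c.D) or mask.shape[1:] != (c.L, c.K):
            raise ShapeError(
                f"input shape {inputs.shape} does not match config "
                f"(L={c.L}, K={c.K}, D={c.D})")
        return self.forward(inputs.astype(DTYPE), mask)


class TransformerImputer(_ImputerBase):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.proj = Linear(c.D + 1, c.model_dim, rng)   # shared across keypoints
        self.time_emb = Embedding(c.L, c.model_dim, rng)
        # learnable time embedding, initialized sinusoidally so attention can
        # express relative-time alignment from the first steps
        pos = np.arange(c.L)[:, None]
        i = np.arange(c.model_dim // 2)[None, :]
        freq = 1.0 / (10000.0 ** (2 * i / c.model_dim))
        pe = np.empty((c.L, c.model_dim), dtype=DTYPE)
        pe[:, 0::2] = np.sin(pos * freq)
        pe[:, 1::2] = np.cos(pos * freq)
        self.time_emb.weight.data = pe
        self.kp_emb = Embedding(c.K, c.model_dim, rng)
        self.mask_emb = Embedding(2, c.model_dim, rng)
        self.layers = [TransformerEncoderLayer(c.model_dim, c.n_heads,
                                               c.ff_dim, c.dropout, rng)
                       for _ in range(c.n_layers)]
        self.ln_final = LayerNorm(c.model_dim)
        self.head = Linear(c.model_dim, c.D * (2 if c.proba else 1), rng)
        # token index grids, fixed for the configured (L, K)
        self._t_idx = np.repeat(np.arange(c.L), c.K)
        self._k_idx = np.tile(np.arange(c.K), c.L)

    def encode(self, inputs: np.ndarray, mask: np.ndarray) -> Tensor:
        c = self.config
        B = inputs.shape[0]
        m = mask.astype(DTYPE)[..., None]
        x = Tensor(np.concatenate([inputs, m], axis=-1))   # (B, L, K, D+1)
        tok = self.proj(x).reshape(B, c.L * c.K, c.model_dim)
        tok = tok + self.time_emb(self._t_idx) + self.kp_emb(self._k_idx)
        tok = tok + self.mask_emb(mask.astype(np.int64).reshape(B, c.L * c.K))
        for layer in self.layers:
            tok = layer(tok)
        return self.ln_final(tok)                          # (B, L*K, dim)

    def forward(self, inputs, mask):
        out = self.head(self.encode(inputs, mask))
        return self._split_head(out, inputs.shape[0])

    def latent(self, inputs, mask) -> np.ndarray:
        """Mean over tokens of the final encoder layer, (B, model_dim)."""
        with no_grad():
            return self.encode(inputs.astype(DTYPE), mask).data.mean(axis=1)


class GRUImputer(_ImputerBase):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        n_in = c.K * (c.D + 1)
        self.layers = []
        for i in range(c.n_layers):
            self.layers.append(BiGRULayer(n_in if i == 0 else 2 * c.hidden,
                                          c.hidden, rng))
        self.drop = Dropout(c.dropout, rng)
        self.head = Linear(2 * c.hidden, c.K * c.D * (2 if c.proba else 1), rng)

    def encode(self, inputs: np.ndarray, mask: np.ndarray) -> Tensor:
        c = self.config
        B = inputs.shape[0]
        m = mask.astype(DTYPE)[..., None]
        x = Tensor(np.concatenate([inputs, m], axis=-1).reshape(B, c.L, -1))
        for layer in self.layers:
            x = layer(x)
        return x                                           # (B, L, 2*hidden)

    def forward(self, inputs, mask):
        out = self.head(self.drop(self.encode(inputs, mask)))
        return self._split_head(out, inputs.shape[0])

    def latent(self, inputs, mask) -> np.ndarray:
        with no_grad():
            return self.encode(inputs.astype(DTYPE), mask).data.mean(axis=1)


class _TCNBlock(Module):
    def __init__(self, c_in: int, c_out: int, dilation: int,
                 dropout: float, rng: np.random.Generator):
        self.conv1 = CausalConv1d(c_in, c_out, 2, dilation, rng)
        self.conv2 = CausalConv1d(c_out, c_out, 2, dilation, rng)
        self.drop = Dropout(dropout, rng)
        self.res = Linear(c_in, c_out, rng, bias=False) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop(self.conv1(x).relu())
        h = self.drop(self.conv2(h).relu())
        return h + (self.res(x) if self.res is not None else x)


class TCNImputer(_ImputerBase):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        n_in = c.K * (c.D + 1)
        dilations = [2 ** i for i in range(c.n_layers)]
        self.blocks = []
        for i, d in enumerate(dilations):
            self.blocks.append(_TCNBlock(n_in if i == 0 else c.hidden,
                                         c.hidden, d, c.dropout, rng))
        self.head = Linear(c.hidden, c.K * c.D * (2 if c.proba else 1), rng)

    def forward(self, inputs, mask):
        c = self.config
        B = inputs.shape[0]
        m = mask.astype(DTYPE)[..., None]
        x = Tensor(np.concatenate([inputs, m], axis=-1).reshape(B, c.L, -1))
        for block in self.blocks:
            x = block(x)
        return self._split_head(self.head(x), B)


def build_model(config: ModelConfig, seed: int = 0) -> _ImputerBase:
    """Instantiate a backbone with seeded initialization."""
    rng = np.random.default_rng(seed)
    cls = {"transformer": TransformerImputer, "gru": GRUImputer,
           "tcn": TCNImputer}[config.backbone]
    return cls(config, rng)


def predict(model: _ImputerBase, masked: MaskedSample) -> Prediction:
    """Run one masked sample through the model in eval mode (no graph)."""
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            mean, std = model(masked.input[None], masked.gap_mask[None])
    finally:
        model.train(was_training)
    return Prediction(mean.data[0].astype(np.float64),
                      None if std is None else std.data[0].astype(np.float64))


def predict_batch(model: _ImputerBase, inputs: np.ndarray, masks: np.ndarray
                  ) -> Prediction:
    """Eval-mode forward on a (B, L, K, D) batch."""
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            mean, std = model(inputs, masks)
    finally:
        model.train(was_training)
    return Prediction(mean.data.astype(np.float64),
                      None if std is None else std.data.astype(np.float64))


def extract_latent(model: _ImputerBase, masked: MaskedSample) -> np.ndarray:
    """Fixed-length latent vector (mean-pooled encoder output).

    Available for the transformer and GRU backbones; the TCN has no
    pre-head representation of fixed width and is unsupported.
    """
    if not hasattr(model, "latent"):
        raise ConfigError("latent extraction is unsupported for this backbone")
    was_training = model.training
    model.eval()
    try:
        return model.latent(masked.input[None], masked.gap_mask[None])[0]
    finally:
        model.train(was_training)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: _ImputerBase, path: str | Path,
                    extra: dict | None = None) -> Path:
    """Single-file archive: config JSON + parameter arrays (npz)."""
    path = Path(path)
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config"] = np.asarray(json.dumps(asdict(model.config)))
    payload["extra"] = np.asarray(json.dumps(extra or {}))
    np.savez(path, **payload)
    return path


def load_checkpoint(path: str | Path) -> tuple[_ImputerBase, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        config = ModelConfig(**json.loads(str(z["config"])))
        extra = json.loads(str(z["extra"]))
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    model = build_model(config, seed=0)
    model.load_state_dict(state)
    return model, extra
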