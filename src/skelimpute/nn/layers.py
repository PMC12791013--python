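"""Neural-network building blocks on top of the autodiff engine.

Initialization follows the common fan-in uniform scheme for linear maps and
recurrences (U(-1/sqrt(fan_in), +1/sqrt(fan_in))) with an explicit seeded
generator, so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

DTYPE = np.float32


class Module:
    """Base class with parameter discovery through attributes and lists."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            raise KeyError("state dict keys do not match model parameters")
        for name, arr in state.items():
            if params[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            params[name].data = arr.astype(params[name].data.dtype).copy()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, val in vars(self).items():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(DTYPE),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        s = 1.0 / np.sqrt(n_in)
        self.W = _param(rng, (n_in, n_out), s)
        self.b = _param(rng, (n_out,), s) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class Embedding(Module):
    """Lookup table: integer indices -> learned vectors."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(
            (rng.standard_normal((n, dim)) / np.sqrt(dim)).astype(DTYPE),
            requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep.astype(x.data.dtype))


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("model dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, dim = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, T, 3, h, dh).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]          # each (B, h, T, dh)
        q = q * np.float32(1.0 / np.sqrt(dh))     # scale before the big matmul
        attn = (q @ k.transpose((0, 1, 3, 2))).softmax(axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, dim)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + MHA(LN(x)), then x + FFN(LN(x)).

    Pre-normalization keeps gradients well-scaled from the first step, which
    matters for the short desk-scale trainings this package targets.
    """

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 dropout: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)))
        return x + self.drop(self.ff2(self.ff1(self.ln2(x)).relu()))


class GRULayer(Module):
    """Single-direction GRU over a (B, L, n_in) sequence.

    Gate equations follow the standard formulation:
    r = sigma(W_ir x + W_hr h + b), z = sigma(W_iz x + W_hz h + b),
    n = tanh(W_in x + r * (W_hn h + b_hn)), h' = (1 - z) n + z h.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        s = 1.0 / np.sqrt(hidden)
        self.W_ih = _param(rng, (n_in, 3 * hidden), s)
        self.W_hh = _param(rng, (hidden, 3 * hidden), s)
        self.b_ih = _param(rng, (3 * hidden,), s)
        self.b_hh = _param(rng, (3 * hidden,), s)
        self.hidden = hidden
        self.reverse = reverse

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden
        xg = x @ self.W_ih + self.b_ih          # (B, L, 3H) precomputed
        h = Tensor(np.zeros((B, H), dtype=DTYPE))
        outs: list[Tensor] = []
        steps = range(L - 1, -1, -1) if self.reverse else range(L)
        for t in steps:
            g_in = xg[:, t, :]
            g_h = h @ self.W_hh + self.b_hh
            r = (g_in[:, :H] + g_h[:, :H]).sigmoid()
            z = (g_in[:, H:2 * H] + g_h[:, H:2 * H]).sigmoid()
            n = (g_in[:, 2 * H:] + r * g_h[:, 2 * H:]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h.reshape(B, 1, H))
        if self.reverse:
            outs = outs[::-1]
        return Tensor.concat(outs, axis=1)       # (B, L, H)


class BiGRULayer(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = GRULayer(n_in, hidden, rng, reverse=False)
        self.bwd = GRULayer(n_in, hidden, rng, reverse=True)

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor.concat([self.fwd(x), self.bwd(x)], axis=-1)


class CausalConv1d(Module):
    """Dilated causal convolution over (B, L, C_in) -> (B, L, C_out).

    Left-pads by (kernel_size - 1) * dilation so output frame t only sees
    inputs at frames <= t.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(c_in * kernel_size)
        self.W = _param(rng, (kernel_size * c_in, c_out), s)
        self.b = _param(rng, (c_out,), s)
        self.kernel_size = kernel_size
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        k, d = self.kernel_size, self.dilation
        pad = (k - 1) * d
        xp = x.pad_axis(1, pad, 0)                # (B, L+pad, C)
        taps = [xp[:, i * d:i * d + L, :] for i in range(k)]
        unfolded = Tensor.concat(taps, axis=-1)   # (B, L, k*C)
        return unfolded @ self.W + self.b
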