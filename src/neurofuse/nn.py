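"""Neural building blocks on the autodiff core.

Contains the generic layers shared by the two encoder pathways and the
fusion / classification heads: linear maps, dropout, layer norm, 3-D batch
norm, a bidirectional LSTM, masked multi-head self-attention, a pre-norm
Transformer encoder layer, sinusoidal positional encoding, and the AdamW
optimizer with global-norm gradient clipping.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import (Parameter, Tensor, concat, conv3d, lstm_pass,
                       softmax)

__all__ = [
    "Module", "Linear", "Dropout", "LayerNorm", "BatchNorm3d", "Conv3d",
    "BiLSTM", "MultiHeadSelfAttention", "TransformerEncoderLayer",
    "sinusoidal_positions", "AdamW", "count_parameters",
]


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        def walk(value, full):
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(item, f"{full}[{i}]")

        for name, value in vars(self).items():
            yield from walk(value, f"{prefix}.{name}" if prefix else name)

    def modules(self):
        def walk(value):
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from walk(item)

        yield self
        for value in vars(self).values():
            yield from walk(value)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry: {name}")

    def named_buffers(self, prefix: str = ""):
        def walk(value, full, is_running):
            if isinstance(value, np.ndarray) and is_running:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(item, f"{full}[{i}]", is_running)

        for name, value in vars(self).items():
            yield from walk(value, f"{prefix}.{name}" if prefix else name,
                            name.startswith("running_"))


def count_parameters(module: Module) -> int:
    return sum(p.size for p in module.parameters())


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_xavier(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * mask


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class BatchNorm3d(Module):
    """Batch norm over (B, C, D, H, W): batch statistics while training,
    exponential running averages (momentum 0.1) in eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            xhat = xc / (var + self.eps).sqrt()
        else:
            shape = (1, -1, 1, 1, 1)
            xhat = (x - self.running_mean.reshape(shape)) / np.sqrt(
                self.running_var.reshape(shape) + self.eps)
        shape = (1, -1, 1, 1, 1)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = c_in * kernel ** 3
        fan_out = c_out * kernel ** 3
        self.weight = Parameter(
            _xavier(rng, fan_in, fan_out,
                    shape=(c_out, c_in, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class _LSTMDirection(Module):
    """One direction of an LSTM, with per-timestep mask gating.

    At masked (padded) timesteps the hidden and cell state are carried over
    unchanged, so a sequence padded at either end produces exactly the same
    valid-position states as the unpadded sequence.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        s = 1.0 / math.sqrt(hidden)
        self.w_x = Parameter(rng.uniform(-s, s, size=(d_in, 4 * hidden)))
        self.w_h = Parameter(rng.uniform(-s, s, size=(hidden, 4 * hidden)))
        self.b = Parameter(np.zeros(4 * hidden))
        self.hidden = hidden

    def forward(self, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
        return lstm_pass(x, self.w_x, self.w_h, self.b, mask,
                         reverse=reverse)


class BiLSTM(Module):
    """Bidirectional LSTM returning [forward ‖ backward] per timestep."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMDirection(d_in, hidden, rng)
        self.bwd = _LSTMDirection(d_in, hidden, rng)
        self.d_in = d_in
        self.hidden = hidden

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ValueError(
                f"input feature dim {x.shape[-1]} != configured {self.d_in}")
        hf = self.fwd(x, mask, reverse=False)
        hb = self.bwd(x, mask, reverse=True)
        return concat([hf, hb], axis=-1)


def sinusoidal_positions(T: int, d: int) -> np.ndarray:
    """Standard fixed sinusoidal positional-encoding table (T, d)."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


class MultiHeadSelfAttention(Module):
    """Self-attention with additive -inf masking of padded key positions.

    Masked keys receive exactly zero attention weight; rows therefore form a
    probability distribution over the valid keys only.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose((0, 2, 1, 3))

        q, k, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        bias = np.where(mask[:, None, None, :] > 0, 0.0, -np.inf)
        if np.isinf(bias).all(axis=-1).any():
            raise ValueError("a sample has no valid timesteps")
        attn = softmax(scores + bias, axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # B,h,T,dh
        out = out.transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.w_o(out)


class TransformerEncoderLayer(Module):
    """Pre-norm Transformer encoder layer (attention + position-wise FFN)."""

    def __init__(self, d_model: int, n_heads: int, ffn_mult: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_mult * d_model, rng)
        self.ffn2 = Linear(ffn_mult * d_model, d_model, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x), mask))
        x = x + self.drop2(self.ffn2(self.ffn1(self.norm2(x)).relu()))
        return x


class AdamW:
    """AdamW with decoupled weight decay and optional global-norm clipping."""

    def __init__(self, params, lr: float = 5e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01,
                 clip_norm: float | None = 5.0):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
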