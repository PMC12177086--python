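"""Neural-network building blocks on top of :mod:`sonomil.autograd`.

Layers follow the conventional Module pattern: parameters are
:class:`~sonomil.autograd.Tensor` objects with ``requires_grad=True``,
collected recursively for the optimizer and for flat ``state_dict``
checkpointing. All weight initialisation draws from an explicit
``numpy.random.Generator`` so model construction is reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, concat


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / math.sqrt(n_in)
        self.weight = parameter(rng.uniform(-bound, bound, (n_in, n_out)))
        self.bias = parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        self.stride = stride
        self.padding = padding
        fan_in = c_in * kernel * kernel
        bound = math.sqrt(2.0 / fan_in)
        self.weight = parameter(rng.normal(0.0, bound, (c_out, c_in, kernel, kernel)))
        self.bias = parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import conv2d
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class ConvTranspose2x2(Module):
    """Kernel-2/stride-2 transposed convolution (exact 2x spatial upscale)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        bound = math.sqrt(2.0 / (c_in * 4))
        self.weight = parameter(rng.normal(0.0, bound, (c_in, c_out, 2, 2)))
        self.bias = parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import conv_transpose2x2
        return conv_transpose2x2(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.eps = eps
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gamma + self.beta


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 out_dim: int | None = None):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim if out_dim is not None else dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class MultiheadAttention(Module):
    """Scaled dot-product attention; supports cross-attention and key masks."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def _split(self, x: Tensor, b: int, s: int) -> Tensor:
        dh = self.dim // self.heads
        return x.reshape(b, s, self.heads, dh).transpose(0, 2, 1, 3)

    def forward(self, query: Tensor, key: Tensor, value: Tensor,
                key_valid: np.ndarray | None = None) -> Tensor:
        b, sq, _ = query.shape
        sk = key.shape[1]
        dh = self.dim // self.heads
        q = self._split(self.q_proj(query), b, sq)
        k = self._split(self.k_proj(key), b, sk)
        v = self._split(self.v_proj(value), b, sk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if key_valid is not None:
            bias = np.where(np.asarray(key_valid, bool), 0.0, -1e9)
            scores = scores + Tensor(bias[:, None, None, :])
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, sq, self.dim)
        return self.out_proj(out)


class TransformerBlock(Module):
    """Pre-norm self-attention block without positional structure."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor, key_valid: np.ndarray | None = None) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, h, key_valid=key_valid)
        return x + self.mlp(self.norm2(x))


class AdamW:
    """Adam with decoupled weight decay and a constant learning rate."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def binary_cross_entropy(p: Tensor, target: np.ndarray | float,
                         eps: float = 1e-7) -> Tensor:
    """Mean BCE between probabilities ``p`` and targets in [0, 1].

    Probabilities are clamped to [eps, 1-eps] before the logarithms.
    """
    y = np.asarray(target, dtype=np.float64)
    pc = p.clip(eps, 1.0 - eps)
    loss = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log())
    return loss.mean()


def stack_batch(arrays) -> Tensor:
    return Tensor(np.stack([np.asarray(a, dtype=np.float64) for a in arrays]))
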