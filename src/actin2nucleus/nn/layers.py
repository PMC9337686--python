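"""Network building blocks: linear/conv layers, normalizations, attention.

A tiny ``Module`` system collects :class:`~actin2nucleus.nn.autograd.Tensor`
parameters recursively so the optimizer and the checkpoint code can address
them by dotted name.  Initialization is He-style for conv/linear weights and
is driven entirely by the generator passed at construction, so a model built
twice from the same seed has bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Linear", "Conv2d", "PixelNorm", "LayerNorm",
    "MultiHeadSelfAttention", "TransformerBlock", "Adam",
]


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.data.shape)


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.w = Tensor(np.zeros((n_in, n_out), np.float32), requires_grad=True)
        else:
            self.w = _he(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.w = _he(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, stride=self.stride, padding=self.padding)


class PixelNorm(Module):
    """Per-pixel feature normalization to unit RMS across channels (NCHW)."""

    def __init__(self, eps: float = 1e-8):
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        ms = (x * x).mean(axis=1, keepdims=True)
        return x * (ms + self.eps) ** -0.5


class LayerNorm(Module):
    """Layer normalization over the last (channel) axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gain + self.bias


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        B, N, C = z.shape
        h, d = self.heads, self.dim // self.heads
        qkv = self.qkv(z)                                 # (B, N, 3C)
        qkv = qkv.reshape(B, N, 3, h, d).transpose(2, 0, 3, 1, 4)  # (3,B,h,N,d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder layer: residual MSA then residual MLP."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        z = self.attn(self.ln1(z)) + z
        z = self.fc2(self.fc1(self.ln2(z)).gelu()) + z
        return z


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
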