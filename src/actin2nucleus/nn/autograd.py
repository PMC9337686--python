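"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the translator network needs:
broadcast-aware arithmetic, batched matmul, reductions, shape ops, the
activations used by the generator/discriminator, a 2D convolution built on
im2col, and nearest-neighbour upsampling.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via a topological sort of the
recorded graph.

Everything is float32 by default; the graph is rebuilt on every forward
pass (define-by-run), so training loops stay pure functions of their
inputs and seeds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), back)

    def __getitem__(self, idx):
        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), back)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), back)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -----------------------------------------
    def abs(self):
        sign = np.sign(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), back)

    def sqrt(self):
        return self ** 0.5

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        scale = np.where(pos, 1.0, slope).astype(np.float32)

        def back(g):
            if self.requires_grad:
                self._accum(g * scale)

        return self._make(self.data * scale, (self,), back)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), back)

    def gelu(self):
        """tanh-approximation GELU."""
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def back(g):
            if self.requires_grad:
                dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x ** 2)
                self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return self._make(out_data, (self,), back)

    def softplus(self):
        """log(1 + exp(x)), computed stably; used for GAN losses on logits."""
        out_data = np.logaddexp(0.0, self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), back)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), back)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        a, b = self.data, other.data

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(a, b), (self, other), back)

    __matmul__ = matmul

    # -- image ops -----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               stride: int = 1, padding: int = 1):
        """NCHW convolution via im2col.

        weight: (C_out, C_in, kh, kw); bias: (C_out,).
        """
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Co, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho = (H + 2 * padding - kh) // stride + 1
        Wo = (W + 2 * padding - kw) // stride + 1
        # (B, C, kh, kw, Ho, Wo) view
        view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        view = view[:, :, ::stride, ::stride]          # (B, C, Ho, Wo, kh, kw)
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
        wmat = w.reshape(Co, C * kh * kw).T            # (C*kh*kw, Co)
        out_data = np.matmul(cols, wmat)               # (B, Ho*Wo, Co)
        if bias is not None:
            out_data = out_data + bias.data
        out_data = out_data.transpose(0, 2, 1).reshape(B, Co, Ho, Wo)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def back(g):
            gcols = g.reshape(B, Co, Ho * Wo).transpose(0, 2, 1)  # (B,HoWo,Co)
            if bias is not None and bias.requires_grad:
                bias._accum(gcols.sum(axis=(0, 1)))
            if weight.requires_grad:
                gw = np.einsum("bnc,bnk->ck", gcols, cols, optimize=True)
                weight._accum(gw.reshape(Co, C, kh, kw))
            if self.requires_grad:
                gx_cols = np.matmul(gcols, wmat.T)     # (B, HoWo, C*kh*kw)
                gx_cols = gx_cols.reshape(B, Ho, Wo, C, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * Ho:stride,
                            j:j + stride * Wo:stride] += \
                            gx_cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accum(gxp)

        return self._make(out_data, parents, back)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of an NCHW tensor."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def back(g):
            if self.requires_grad:
                B, C, H2, W2 = g.shape
                gr = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
                self._accum(gr)

        return self._make(out_data, (self,), back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)
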