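"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order accumulating gradients.  Only the operations the affinity networks
need are implemented (broadcast arithmetic, batched matmul, activations,
softmax/log-softmax, reductions, slicing/concat, embedding lookup, 2D
convolution via im2col, max pooling, dropout, cross-entropy).  Gradients of
every op are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "set_default_dtype", "get_default_dtype"]

# float32 is the working precision (memory-bandwidth bound workloads);
# gradient-check tests switch to float64.
_DTYPE = np.dtype(np.float32)


def set_default_dtype(dtype) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dtype)


def get_default_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=_DTYPE)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        d = self.data
        # np.power with a float exponent is far slower than the algebraic
        # special cases the networks actually use
        if e == 2.0:
            out_data = d * d
        elif e == 3.0:
            out_data = d * d * d
        elif e == 0.5:
            out_data = np.sqrt(d)
        elif e == -0.5:
            out_data = 1.0 / np.sqrt(d)
        elif e == -1.0:
            out_data = 1.0 / d
        else:
            out_data = np.power(d, e)

        def bw(g):
            if e == 2.0:
                deriv = 2.0 * d
            elif e == 3.0:
                deriv = 3.0 * d * d
            elif e == 0.5:
                deriv = 0.5 / out_data
            elif e == -0.5:
                deriv = -0.5 * out_data / d
            elif e == -1.0:
                deriv = -out_data * out_data
            else:
                deriv = e * np.power(d, e - 1.0)
            self._accum(g * deriv)

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                if a.ndim == 1:
                    self._accum(g * b)
                    other._accum(g * a)
                    return
                self._accum(np.expand_dims(g, -1) * b)
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))
                return
            if a.ndim == 1:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                other._accum(np.expand_dims(a, -1) * g)
                return
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # ------------------------------------------------------------ activations
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._make(s, (self,), bw)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def bw(g):
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), bw)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(self.data[key], (self,), bw)

    @staticmethod
    def concat(tensors, axis: int = 0):
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
        )

    @staticmethod
    def stack(tensors, axis: int = 0):
        return Tensor.concat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors], axis=axis)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_along(self, axis: int):
        """Max reduction along one axis (used for global graph pooling)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

        def bw(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # ---------------------------------------------------------- lookups / nn
    @staticmethod
    def embedding(weight: "Tensor", idx: np.ndarray):
        """Row lookup ``weight[idx]`` with scatter-add backward."""
        idx = np.asarray(idx)

        def bw(g):
            full = np.zeros_like(weight.data)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, weight.shape[1]))
            weight._accum(full)

        return Tensor._make(weight.data[idx], (weight,), bw)

    def dropout(self, p: float, rng: np.random.Generator):
        """Inverted dropout; call only in training mode."""
        if p <= 0:
            return self
        mask = ((rng.random(self.shape) >= p) / (1.0 - p)).astype(self.data.dtype)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor"):
        """Valid, unit-stride 2D convolution.

        ``self``: (N, C, H, W); ``weight``: (F, C, kh, kw); ``bias``: (F,).
        """
        x, w = np.ascontiguousarray(self.data), weight.data
        N, C, H, W = x.shape
        F, _, kh, kw = w.shape
        oh, ow = H - kh + 1, W - kw + 1
        s = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, shape=(N, C, oh, ow, kh, kw), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
        )
        cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * oh * ow, C * kh * kw)
        wf = w.reshape(F, C * kh * kw)
        out_data = (cols2 @ wf.T).reshape(N, oh, ow, F).transpose(0, 3, 1, 2) + bias.data.reshape(1, F, 1, 1)

        def bw(g):
            gf = g.transpose(0, 2, 3, 1).reshape(N * oh * ow, F)
            weight._accum((gf.T @ cols2).reshape(w.shape))
            bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = (gf @ wf).reshape(N, oh, ow, C, kh, kw)
                gx = np.zeros_like(x)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i : i + oh, j : j + ow] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                self._accum(gx)

        return Tensor._make(out_data, (self, weight, bias), bw)

    def max_pool2d(self, kernel: int, stride: int):
        """Max pooling over (kernel x kernel) windows with the given stride."""
        x = np.ascontiguousarray(self.data)
        N, C, H, W = x.shape
        oh = (H - kernel) // stride + 1
        ow = (W - kernel) // stride + 1
        s = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x,
            shape=(N, C, oh, ow, kernel, kernel),
            strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        )
        flat = windows.reshape(N, C, oh, ow, kernel * kernel)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gx = np.zeros_like(x)
            ki, kj = np.unravel_index(arg, (kernel, kernel))
            n_i, c_i, oh_i, ow_i = np.indices(arg.shape)
            rows = oh_i * stride + ki
            cols = ow_i * stride + kj
            np.add.at(gx, (n_i, c_i, rows, cols), g)
            self._accum(gx)

        return Tensor._make(out_data, (self,), bw)

    def normalize(self, gamma: "Tensor", beta: "Tensor", mu, inv, axes, stats_from_x: bool):
        """Fused (layer/batch) normalisation: ``(x - mu) * inv * gamma + beta``.

        ``mu``/``inv`` are precomputed numpy arrays broadcastable to ``x``.
        When ``stats_from_x`` is true they are the batch statistics of ``x``
        itself and the backward pass accounts for their dependence on ``x``;
        otherwise (running statistics at eval time) they are constants.
        """
        xn = (self.data - mu) * inv
        out_data = xn * gamma.data + beta.data

        def bw(g):
            gamma._accum(_unbroadcast(g * xn, gamma.shape))
            beta._accum(_unbroadcast(g, beta.shape))
            if not self.requires_grad:
                return
            dxn = g * gamma.data
            if stats_from_x:
                m1 = dxn.mean(axis=axes, keepdims=True)
                m2 = (dxn * xn).mean(axis=axes, keepdims=True)
                self._accum(inv * (dxn - m1 - xn * m2))
            else:
                self._accum(inv * dxn)

        return Tensor._make(out_data, (self, gamma, beta), bw)

    def cross_entropy(self, targets: np.ndarray):
        """Mean cross-entropy of row logits ``self`` (n, V) against int targets."""
        targets = np.asarray(targets)
        n = self.shape[0]
        z = self.data - self.data.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        logp = z - lse
        loss = -logp[np.arange(n), targets].mean()
        soft = np.exp(logp)

        def bw(g):
            grad = soft.copy()
            grad[np.arange(n), targets] -= 1.0
            self._accum(g * grad / n)

        return Tensor._make(loss, (self,), bw)
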