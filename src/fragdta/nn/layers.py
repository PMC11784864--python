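"""Neural network layers built on the autograd :class:`~fragdta.nn.tensor.Tensor`.

Layers hold their parameters as Tensors with ``requires_grad=True`` and are
initialised from an explicit ``numpy.random.Generator`` so that every model
in the package is bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Conv2d",
    "BatchNorm2d",
    "Dropout",
]


class Module:
    """Base class: parameter collection, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.append(item)
                        out.extend(item.modules())
        return out

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values() if isinstance(v, Tensor) and v.requires_grad]
        for m in self.modules():
            params.extend(
                v for v in m.__dict__.values() if isinstance(v, Tensor) and v.requires_grad
            )
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- persistence ------------------------------------------------------
    def _named_arrays(self, prefix: str = "") -> dict:
        out = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v._named_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)) and any(isinstance(i, Module) for i in v):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item._named_arrays(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self._named_arrays().items()}

    def load_state_dict(self, state: dict) -> None:
        arrays = self._named_arrays()
        missing = set(arrays) ^ set(state)
        if missing:
            raise KeyError(f"state dict keys do not match module: {sorted(missing)}")
        for k, arr in arrays.items():
            arr[...] = state[k]


class Linear(Module):
    """Affine map with Glorot-uniform initialisation."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, (num_embeddings, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return Tensor.embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        return x.normalize(self.gamma, self.beta, mu, inv, axes=(-1,), stats_from_x=True)


class Conv2d(Module):
    """Valid, unit-stride 2D convolution with He-uniform initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
            var = x.data.var(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.ravel().astype(np.float64)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.ravel().astype(np.float64)
            inv = 1.0 / np.sqrt(var + self.eps)
            return x.normalize(self.gamma, self.beta, mu, inv, axes=(0, 2, 3), stats_from_x=True)
        mu = self.running_mean.reshape(1, c, 1, 1).astype(x.data.dtype)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1).astype(x.data.dtype)
        return x.normalize(self.gamma, self.beta, mu, inv, axes=(0, 2, 3), stats_from_x=False)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        return x.dropout(self.p, self.rng)
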