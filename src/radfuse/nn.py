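"""Neural-network building blocks on top of the autodiff engine.

Layers follow the usual conventions: parameters are :class:`~radfuse._tensor.Tensor`
objects with ``requires_grad=True``, batch-norm running statistics are plain
arrays (buffers), and modules switch between training and evaluation mode with
:meth:`Module.train` / :meth:`Module.eval`.  ``state_dict`` / ``load_state_dict``
give flat, copyable checkpoints keyed by dotted attribute paths.
"""

from __future__ import annotations

import copy
from typing import Iterator

import numpy as np

from ._tensor import Tensor, as_tensor, batch_norm, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm1d",
    "BatchNorm2d",
    "Sequential",
    "ReLU",
    "SiLU",
    "MLP",
    "Adam",
]


class Module:
    """Base class: parameter/buffer discovery, mode switching, checkpoints."""

    def __init__(self):
        self.training = True
        self._buffers: list[str] = []

    # attribute walk shared by parameters() / state_dict()
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        params = [
            v for v in vars(self).values()
            if isinstance(v, Tensor) and v.requires_grad
        ]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def train(self) -> "Module":
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                state[prefix + name] = value.data.copy()
            elif name in self._buffers:
                state[prefix + name] = np.array(value, copy=True)
        for name, child in self._children():
            state.update(child.state_dict(prefix=f"{prefix}{name}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = prefix + name
            if isinstance(value, Tensor) and value.requires_grad and key in state:
                value.data = np.array(state[key], dtype=value.data.dtype, copy=True)
            elif name in self._buffers and key in state:
                setattr(self, name, np.array(state[key], copy=True))
        for name, child in self._children():
            child.load_state_dict(state, prefix=f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    """Affine map ``x @ W.T + b`` with Glorot-normal initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        std = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_dim, in_dim)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True)
        self.in_dim, self.out_dim = in_dim, out_dim

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input width {self.in_dim}, got {x.shape[-1]}")
        return x @ self.weight.swapaxes(0, 1) + self.bias


class Conv2d(Module):
    """Strided 2-D convolution with He-normal initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dtype=np.float64):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class _BatchNorm(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._buffers = ["running_mean", "running_var"]
        self.momentum = momentum
        self.eps = eps
        self.num_features = num_features

    def _normalize(self, x: Tensor, axes: tuple[int, ...], shape) -> Tensor:
        if self.training:
            out, mu, var = batch_norm(
                x, self.gamma.reshape(shape), self.beta.reshape(shape),
                axes=axes, eps=self.eps,
            )
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(-1)
            return out
        mu = self.running_mean.reshape(shape)
        var = self.running_var.reshape(shape)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        scale = self.gamma.reshape(shape) * inv_std
        return x * scale + (self.beta.reshape(shape) - mu.astype(x.dtype) * scale)


class BatchNorm1d(_BatchNorm):
    """Batch normalization over the batch axis of a (B, C) matrix."""

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[-1] != self.num_features:
            raise ValueError(
                f"expected {self.num_features} channels, got {x.shape[-1]}"
            )
        return self._normalize(x, (0,), (1, self.num_features))


class BatchNorm2d(_BatchNorm):
    """Batch normalization over (batch, height, width) of an NCHW tensor."""

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.num_features:
            raise ValueError(f"expected {self.num_features} channels, got {x.shape[1]}")
        return self._normalize(x, (0, 2, 3), (1, self.num_features, 1, 1))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x).relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x).silu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MLP(Module):
    """One-hidden-layer perceptron with a smooth nonlinearity."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.net = Sequential(
            Linear(in_dim, hidden_dim, rng, dtype=dtype),
            SiLU(),
            Linear(hidden_dim, out_dim, rng, dtype=dtype),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Adam:
    """Adam with (coupled) L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / bias1
            v_hat = self._v[i] / bias2
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clone_state(module: Module) -> dict[str, np.ndarray]:
    """Deep copy of a module's checkpointable state."""
    return copy.deepcopy(module.state_dict())
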